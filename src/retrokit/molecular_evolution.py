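"""Constraint, age, orthology and gene-traffic statistics for retrocopies.

Ka/Ks is computed with the Nei-Gojobori (1986) counting method: per-codon
synonymous/nonsynonymous site fractions averaged over both sequences,
observed differences resolved by averaging over all orderings of the
single-nucleotide steps (pathways through stop codons excluded when any
stop-free pathway exists), and Jukes-Cantor multiple-hit correction.  Ks < 2
marks a retrocopy as young.  Orthology between species is called from
pairwise sequence alignment at strict >80% identity, >80% coverage, >50 bp
thresholds; origination branches are placed by Dollo parsimony on the
presence profile over a rooted species tree, and per-branch origination
rates are retrocopy counts per million years.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .alignment_engine import CodonAlignment, nt_identity, align_proteins_global

_BASES = "ACGT"


@lru_cache(maxsize=1)
def _codon_table() -> dict[str, str]:
    return {
        a + b + c: str(Seq(a + b + c).translate())
        for a in _BASES for b in _BASES for c in _BASES
    }


@dataclass
class KaKsResult:
    ka: float
    ks: float
    n_sites: float            # nonsynonymous sites (averaged over both seqs)
    s_sites: float
    nd: float                 # observed nonsynonymous differences
    sd: float
    saturated: bool = False

    @property
    def ratio(self) -> float | None:
        """ka/ks; undefined (None) when ks = 0 or distances are saturated."""
        if self.saturated or self.ks == 0:
            return None
        return self.ka / self.ks


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsyn sites, syn sites) for one codon; stop-producing changes count
    as nonsynonymous."""
    table = _codon_table()
    aa = table[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if table[alt] == aa and table[alt] != "*":
                syn += 1 / 3
    return 3.0 - syn, syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences between two codons, averaged over all
    orderings of the observed changes; stop-containing pathways are skipped
    unless every pathway is blocked."""
    table = _codon_table()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        nd = sd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*" and nxt != c2:
                return None
            if table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    results = [walk(order) for order in permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:   # every pathway passes a stop; fall back to all pathways
        valid = []
        for order in permutations(diff_pos):
            nd = sd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if table[nxt] == table[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((nd, sd))
    nd = float(np.mean([v[0] for v in valid]))
    sd = float(np.mean([v[1] for v in valid]))
    return nd, sd


def jukes_cantor(p: float) -> float:
    """JC69 distance; ValueError at saturation (p >= 3/4)."""
    if p >= 0.75:
        raise ValueError("proportion of differences at or beyond saturation")
    return -0.75 * float(np.log(1 - 4 * p / 3)) + 0.0


def ng86_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction on a codon alignment.

    Codon columns containing gaps, N, or a stop codon in either sequence are
    excluded.  Raises ValueError when no comparable codon pair remains;
    saturation (p >= 3/4) is reported on the result rather than raised.
    """
    table = _codon_table()
    pairs = [
        (ca, cb) for ca, cb in alignment.codon_pairs()
        if table[ca] != "*" and table[cb] != "*"
    ]
    if not pairs:
        raise ValueError("no comparable codon pairs in alignment")
    N = S = nd = sd = 0.0
    for ca, cb in pairs:
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        d_n, d_s = _pathway_differences(ca, cb)
        nd += d_n
        sd += d_s
    pn = nd / N if N else 0.0
    ps = sd / S if S else 0.0
    saturated = False
    try:
        ka = jukes_cantor(pn)
    except ValueError:
        ka, saturated = float("nan"), True
    try:
        ks = jukes_cantor(ps)
    except ValueError:
        ks, saturated = float("nan"), True
    return KaKsResult(ka=ka, ks=ks, n_sites=N, s_sites=S, nd=nd, sd=sd,
                      saturated=saturated)


def classify_age(ks: float | None) -> str:
    """young iff Ks < 2; old otherwise; unclassified when Ks undefined."""
    if ks is None or not np.isfinite(ks):
        return "unclassified"
    return "young" if ks < 2 else "old"


def selective_constraint_summary(
    intact_lt_half: int, n_intact: int,
    pseudo_lt_half: int, n_pseudo: int,
    n_total: int | None = None,
) -> dict[str, float]:
    """Shares of retrocopies under strong constraint (Ka/Ks < 0.5).

    The overall share uses the full catalog size as denominator (records with
    undefined Ka/Ks included), the per-class shares their class sizes.
    """
    total = n_total if n_total is not None else n_intact + n_pseudo
    return {
        "intact_lt_half_pct": round(100 * intact_lt_half / n_intact, 1),
        "pseudo_lt_half_pct": round(100 * pseudo_lt_half / n_pseudo, 1),
        "overall_lt_half_pct": round(
            100 * (intact_lt_half + pseudo_lt_half) / total, 1),
    }


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologyPair:
    retro_id_a: str
    retro_id_b: str
    identity: float
    coverage: float
    aligned_length: int


@dataclass
class OrthologyThresholds:
    min_identity: float = 0.8       # strict >
    min_coverage: float = 0.8
    min_length: int = 50            # bp (nt mode) or aa (protein mode)
    level: str = "nt"               # "nt" or "aa"


def find_orthologs(
    seqs_a: Mapping[str, str],
    seqs_b: Mapping[str, str],
    thresholds: OrthologyThresholds | None = None,
) -> tuple[list[OrthologyPair], set[str], set[str]]:
    """All-vs-all orthology between two species' retrocopy sequences.

    Returns (pairs, specific_to_a, specific_to_b); the relation is symmetric.
    """
    th = thresholds or OrthologyThresholds()
    pairs: list[OrthologyPair] = []
    hit_a: set[str] = set()
    hit_b: set[str] = set()
    for ida in sorted(seqs_a):
        for idb in sorted(seqs_b):
            if th.level == "aa":
                aln = align_proteins_global(seqs_a[ida], seqs_b[idb])
                ident = aln.identity
                cov = min(aln.coverage_a, aln.coverage_b)
                length = aln.aligned_length
            else:
                best = None
                sa = seqs_a[ida]
                for sb in (seqs_b[idb],
                           str(Seq(seqs_b[idb]).reverse_complement())):
                    cand = nt_identity(sa, sb)
                    if best is None or cand[0] > best[0]:
                        best = cand
                ident, cov, length = best
            if (ident > th.min_identity and cov > th.min_coverage
                    and length > th.min_length):
                pairs.append(OrthologyPair(ida, idb, ident, cov, length))
                hit_a.add(ida)
                hit_b.add(idb)
    specific_a = set(seqs_a) - hit_a
    specific_b = set(seqs_b) - hit_b
    return pairs, specific_a, specific_b


# ---------------------------------------------------------------------------
# origination branches and rates
# ---------------------------------------------------------------------------

def assign_origin_branch(presence: Iterable[str], tree) -> str:
    """Dollo parsimony: the branch above the MRCA of all carriers.

    ``presence`` is the set of species (leaf labels) carrying the retrocopy;
    ``tree`` is a rooted dendropy Tree or a newick string.  Returns the leaf
    label for single-species presence, otherwise the MRCA node label (or a
    stable label built from the clade's leaf set when the node is unnamed).
    """
    import dendropy

    species = sorted(set(presence))
    if not species:
        raise ValueError("empty presence profile")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    tree.is_rooted = True
    taxa = {t.label for t in tree.taxon_namespace}
    missing = set(species) - taxa
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    if len(species) == 1:
        return species[0]
    mrca = tree.mrca(taxon_labels=species)
    if mrca.label:
        return mrca.label
    clade = sorted(leaf.taxon.label for leaf in mrca.leaf_iter())
    return "+".join(clade)


def example_period_table() -> list[tuple[str, int, float]]:
    """The packaged example branch/count/period table (see data/)."""
    from importlib import resources

    rows = []
    text = (resources.files("retrokit") / "data" /
            "origination_periods.tsv").read_text()
    for line in text.splitlines()[1:]:
        branch, _, count, period = line.split("\t")
        rows.append((branch, int(count), float(period)))
    return rows


def example_species_tree() -> str:
    """The packaged example rooted species tree (newick)."""
    from importlib import resources

    return (resources.files("retrokit") / "data" /
            "lepidoptera_tree.nwk").read_text().strip()


@dataclass
class OriginationBranch:
    branch_id: str
    period_myr: float
    count: int
    rate: float                      # retrocopies per million years, 3 dp


def origination_rates(
    branch_counts: Sequence[tuple[str, int, float]]
) -> tuple[list[OriginationBranch], float]:
    """Per-branch origination rates (count / period, 3 dp) and their mean.

    The mean is taken over the unrounded per-branch rates, then rounded.
    """
    branches: list[OriginationBranch] = []
    raw: list[float] = []
    for bid, count, period in branch_counts:
        if period <= 0:
            raise ValueError(f"branch {bid}: period must be positive")
        rate = count / period
        raw.append(rate)
        branches.append(OriginationBranch(bid, period, count, round(rate, 3)))
    mean_rate = round(float(np.mean(raw)), 3) if raw else float("nan")
    return branches, mean_rate


# ---------------------------------------------------------------------------
# chromosomal traffic
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeCensus:
    """Per-chromosome gene counts and lengths with a Z/A class label."""

    chrom_class: dict[str, str]      # chromosome -> {Z, A}
    n_genes: dict[str, int]
    length: dict[str, int]

    def validate(self) -> None:
        for d in (self.n_genes, self.length):
            if set(d) != set(self.chrom_class):
                raise ValueError("census tables cover different chromosomes")
            if any(v <= 0 for v in d.values()):
                raise ValueError("census counts and lengths must be positive")


def expected_movements(
    census: ChromosomeCensus, total_events: int
) -> dict[str, float]:
    """Null expectation for each movement class under random source/target.

    A source chromosome S contributes events in proportion to its share of
    genes; the destination D is drawn among the other chromosomes in
    proportion to length.  Per-chromosome expectations are aggregated into
    the Z->A / A->Z / A->A movement classes.
    """
    census.validate()
    chroms = sorted(census.chrom_class)
    if not {"Z", "A"} >= set(census.chrom_class.values()):
        raise ValueError("chromosome classes must be Z or A")
    total_genes = sum(census.n_genes.values())
    total_len = sum(census.length.values())
    out = {"Z→A": 0.0, "A→Z": 0.0, "A→A": 0.0, "Z→Z": 0.0}
    for s in chroms:
        src_share = census.n_genes[s] / total_genes
        denom = total_len - census.length[s]
        if denom <= 0:
            continue
        for d in chroms:
            if d == s:
                continue
            e = total_events * src_share * (census.length[d] / denom)
            key = f"{census.chrom_class[s]}→{census.chrom_class[d]}"
            out[key] += e
    return out


def movement_excess(expected: float, observed: int,
                    digits: int = 2) -> float:
    """Percent excess of observed over expected movements."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return round((observed - expected) / expected * 100.0, digits)


@dataclass
class MovementTable:
    rows: list[tuple[str, float, int, float]]   # movement, expected, observed, excess

    @classmethod
    def build(cls, expected: Mapping[str, float],
              observed: Mapping[str, int]) -> "MovementTable":
        rows = []
        for key in ("Z→A", "A→Z", "A→A"):
            e = expected[key]
            o = observed.get(key, 0)
            rows.append((key, e, o, movement_excess(e, o)))
        return cls(rows)
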
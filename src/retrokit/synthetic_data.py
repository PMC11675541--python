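"""Synthetic genomes with planted retrotransposition events.

The generator emulates the data-generating assumptions of the identification
pipeline: multi-exon protein-coding genes on random background sequence,
retrocopy insertions that copy the parent's spliced CDS (introns removed) with
controlled divergence, disruption (frameshift / premature stop), chimeric
fusion and TE flanks, DNA-level tandem gene duplications as negative controls,
and FPKM matrices with testis-biased tissue specificity and parent-correlated
structure.  Every planted event is recorded in a truth table so downstream
stages can be scored for recovery.

Events are written by overwriting equal-length stretches of intergenic
background, so coordinates of previously placed features never shift.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    RepeatFeature,
    write_annotation,
    write_expression_matrix,
    write_genome,
    write_repeat_bed,
)

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if Seq(a + b + c).translate()[0] != "*"
]

RETRO_CLASSES = ("retropseudogene", "retrogene", "chimeric", "intact_unannotated")


@dataclass
class SimulationConfig:
    n_contigs: int = 3
    contig_length: int = 120_000
    n_genes: int = 24
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_cds_length: tuple[int, int] = (90, 330)     # nt, rounded to codons
    intron_length: tuple[int, int] = (60, 700)       # bp
    n_retro_events: int = 20
    substitution_probability: float = 0.02           # per site after insertion
    frameshift_probability: float = 0.02
    premature_stop_probability: float = 0.03
    chimeric_probability: float = 0.55
    retrogene_probability: float = 0.28              # annotated single-exon copy
    te_flank_probability: float = 0.6
    te_class_weights: dict[str, float] = field(
        default_factory=lambda: {"SINE": 0.35, "LINE": 0.45, "LTR": 0.15, "other": 0.05}
    )
    te_length: tuple[int, int] = (300, 1500)
    n_dna_duplications: int = 5
    n_domestication_regions: int = 4
    domestication_overlap_events: int = 2
    domestication_region_length: tuple[int, int] = (4000, 12000)
    tissues: tuple[str, ...] = (
        "testis", "ovary", "silk_gland", "fat_body",
        "head", "midgut", "malpighian_tubule", "epidermis",
    )
    stages: tuple[str, ...] = (
        "L4D3", "L4_molting", "L5D0", "L5D3", "wandering", "pre_pupa",
    )
    testis_bias: float = 4.83        # weight of testis among specific tissues
    specific_fraction: float = 0.3   # fraction of retrocopies tissue-specific
    parent_correlation_weights: tuple[float, float, float] = (0.05, 0.30, 0.65)
    include_zero_pair: bool = True
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.substitution_probability, self.frameshift_probability,
            self.premature_stop_probability, self.chimeric_probability,
            self.retrogene_probability, self.te_flank_probability,
            self.specific_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.te_class_weights.values()) - 1.0) > 1e-9:
            raise ValueError("TE class weights must sum to 1")
        if abs(sum(self.parent_correlation_weights) - 1.0) > 1e-9:
            raise ValueError("parent correlation weights must sum to 1")
        if self.intron_length[0] <= 3:
            raise ValueError("minimum intron length must exceed 3 bp")
        if (self.frameshift_probability + self.premature_stop_probability
                + self.chimeric_probability + self.retrogene_probability) > 1.0:
            raise ValueError("event class probabilities exceed 1")


@dataclass
class TruthRecord:
    event_id: str
    kind: str                       # retro | dna_dup
    parent_gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    introns_removed: int
    disruption: str                 # none | frameshift | premature_stop
    fused_host: str | None
    te_flank: str | None
    expected_class: str             # RETRO_CLASSES, or "none" for DNA controls

    def __post_init__(self) -> None:
        if self.kind == "retro":
            if self.disruption != "none" and self.expected_class != "retropseudogene":
                raise ValueError("disrupted event must be a retropseudogene")
            if self.fused_host and self.expected_class != "chimeric":
                raise ValueError("fused event must be chimeric")
            if self.expected_class not in RETRO_CLASSES:
                raise ValueError(f"bad class {self.expected_class}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end, self.strand)


@dataclass
class ExpressionTruth:
    """Generator bookkeeping for scoring expression-stage recovery."""

    specific_tissue: dict[str, str]          # retro id -> tissue
    mixture_component: dict[str, str]        # retro id -> strong|weak|independent
    zero_pair: str | None


@dataclass
class FixtureBundle:
    config: SimulationConfig
    seed: int
    genome: dict[str, GenomeSequence]
    genes: dict[str, GeneModel]              # includes planted annotations
    truth: list[TruthRecord]
    repeats: list[RepeatFeature]
    regions: list[GenomicInterval]
    expression: ExpressionMatrix | None
    expression_truth: ExpressionTruth | None


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons))
    return "ATG" + body + "TAA"


def simulate_genome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, GenomeSequence], dict[str, GeneModel]]:
    """Random contigs with non-overlapping multi-exon genes, deterministic
    given the seed.  All CDS splits fall on codon boundaries (phase 0)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    contigs = {
        f"chr{i + 1}": bytearray(_random_seq(rng, config.contig_length), "ascii")
        for i in range(config.n_contigs)
    }
    cids = list(contigs)
    genes: dict[str, GeneModel] = {}
    cursors = {cid: int(rng.integers(2500, 4000)) for cid in cids}
    for gi in range(config.n_genes):
        cid = min(cids, key=lambda c: cursors[c])   # keep contigs balanced
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_lens = [
            3 * int(rng.integers(config.exon_cds_length[0] // 3,
                                 config.exon_cds_length[1] // 3 + 1))
            for _ in range(n_exons)
        ]
        total_codons = sum(exon_lens) // 3 - 2
        cds = _random_cds(rng, total_codons)
        assert len(cds) == sum(exon_lens)
        intron_lens = [
            int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            for _ in range(n_exons - 1)
        ]
        pieces: list[tuple[str, bool]] = []   # transcript order
        off = 0
        for k, el in enumerate(exon_lens):
            pieces.append((cds[off : off + el], True))
            off += el
            if k < n_exons - 1:
                pieces.append((_random_seq(rng, intron_lens[k]), False))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            genomic_pieces = [
                (str(Seq(s).reverse_complement()), is_exon)
                for s, is_exon in reversed(pieces)
            ]
        else:
            genomic_pieces = pieces
        gene_len = sum(len(s) for s, _ in genomic_pieces)
        start = cursors[cid]
        if start + gene_len + 2500 > config.contig_length:
            raise ValueError(
                f"gene footprint exceeds contig capacity on {cid}; "
                "reduce n_genes or enlarge contig_length"
            )
        exons = []
        pos = start
        for s, is_exon in genomic_pieces:
            if is_exon:
                exons.append((pos, pos + len(s)))
            contigs[cid][pos : pos + len(s)] = s.encode()
            pos += len(s)
        gid = f"gene{gi + 1:03d}"
        prot = str(Seq(cds).translate())[:-1]
        genes[gid] = GeneModel(
            gene_id=gid, transcript_id=f"{gid}.t1", contig_id=cid,
            strand=strand, exons=exons, cds=list(exons), protein=prot,
        )
        cursors[cid] = pos + int(rng.integers(5500, 8000))
    genome = {
        cid: GenomeSequence(cid, bytes(buf).decode()) for cid, buf in contigs.items()
    }
    return genome, genes


# ---------------------------------------------------------------------------
# planting retrocopies
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.where(rng.random(arr.shape[0]) < p)[0]
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = letters[letters != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _find_slot(
    rng: np.random.Generator, occupied: dict[str, list[tuple[int, int]]],
    contig_lengths: dict[str, int], length: int, margin: int = 2000,
    contig: str | None = None, at: int | None = None, tries: int = 300,
) -> tuple[str, int] | None:
    cids = [contig] if contig else list(contig_lengths)
    if at is not None and contig is not None:
        # adjacency mode: the caller vouches for the upstream neighbour, so the
        # margin is applied downstream only
        lo, hi = at, at + length + margin
        if hi <= contig_lengths[contig] and not any(
            s < hi and lo < e for s, e in occupied[contig]
        ):
            return contig, at
        return None
    for _ in range(tries):
        cid = cids[rng.integers(0, len(cids))]
        clen = contig_lengths[cid]
        if clen <= length + 2 * margin:
            continue
        pos = int(rng.integers(margin, clen - length - margin))
        lo, hi = pos - margin, pos + length + margin
        if not any(s < hi and lo < e for s, e in occupied[cid]):
            return cid, pos
    return None


def plant_retrocopies(
    genome: Mapping[str, GenomeSequence],
    genes: dict[str, GeneModel],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[dict[str, GenomeSequence], list[TruthRecord],
           dict[str, GeneModel], list[RepeatFeature]]:
    """Plant retro events and DNA-duplication controls into intergenic space.

    Returns the mutated genome, the truth table, the annotations added for
    retrogene/chimeric events, and the emitted TE repeat features.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    contigs = {cid: bytearray(g.sequence, "ascii") for cid, g in genome.items()}
    contig_lengths = {cid: g.length for cid, g in genome.items()}
    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in genome}
    for g in genes.values():
        occupied[g.contig_id].append((g.start, g.end))

    parent_pool = [g for g in genes.values() if g.n_exons >= 3]
    if config.n_retro_events and not parent_pool:
        raise ValueError("no genes with >=3 exons to act as parents")

    truth: list[TruthRecord] = []
    new_genes: dict[str, GeneModel] = {}
    repeats: list[RepeatFeature] = []
    # parents cycle through a random permutation so no gene accumulates three
    # or more near-identical copies, which would be indistinguishable from a
    # segmental amplification and (correctly) removed by the caller's
    # DNA-duplication filter
    parent_order = rng.permutation(len(parent_pool)) if parent_pool else []
    class_probs = np.array([
        config.frameshift_probability, config.premature_stop_probability,
        config.chimeric_probability, config.retrogene_probability,
    ])
    class_probs = np.append(class_probs, 1.0 - class_probs.sum())

    def _write(cid: str, pos: int, seq: str) -> None:
        contigs[cid][pos : pos + len(seq)] = seq.encode()
        occupied[cid].append((pos, pos + len(seq)))

    for ev in range(config.n_retro_events):
        eid = f"retro{ev + 1:03d}"
        parent = parent_pool[parent_order[ev % len(parent_pool)]]
        cds = parent.spliced_cds(genome)
        seq = _mutate(rng, cds, config.substitution_probability)
        kind = ["frameshift", "premature_stop", "chimeric", "retrogene", "plain"][
            rng.choice(5, p=class_probs)
        ]
        disruption = "none"
        if kind == "frameshift":
            pos = int(rng.integers(int(0.2 * len(seq)), int(0.8 * len(seq))))
            ins = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                seq = seq[:pos] + _random_seq(rng, ins) + seq[pos:]
            else:
                seq = seq[:pos] + seq[pos + ins:]
            disruption = "frameshift"
        elif kind == "premature_stop":
            n_codons = len(seq) // 3
            ci = int(rng.integers(int(0.2 * n_codons), int(0.7 * n_codons)))
            seq = seq[: 3 * ci] + "TAA" + seq[3 * ci + 3:]
            disruption = "premature_stop"

        fused_host: str | None = None
        if kind == "chimeric":
            hosts = [g for g in genes.values() if g.gene_id != parent.gene_id]
            order = rng.permutation(len(hosts))
            placed = None
            for host in (hosts[i] for i in order):
                strand = host.strand
                gap = int(rng.integers(50, 200))
                at = host.end + gap
                slot = _find_slot(rng, occupied, contig_lengths, len(seq),
                                  margin=500, contig=host.contig_id, at=at)
                if slot:
                    placed = (host, slot[1], strand)
                    break
            if placed is None:
                kind = "plain"          # no room next to any host
            else:
                host, pos, strand = placed
                ins_seq = seq if strand == "+" else str(Seq(seq).reverse_complement())
                _write(host.contig_id, pos, ins_seq)
                fused_host = host.gene_id
                retro_iv = (pos, pos + len(seq))
                host_exon = host.exons[-1]   # genomically nearest to the insertion
                prot = _protein_or_none(seq)
                fid = f"{eid}_fusion"
                new_genes[fid] = GeneModel(
                    gene_id=fid, transcript_id=f"{fid}.t1",
                    contig_id=host.contig_id, strand=strand,
                    exons=sorted([host_exon, retro_iv]), cds=[retro_iv],
                    protein=prot if prot else "M",
                )
                cid = host.contig_id
                truth.append(TruthRecord(
                    eid, "retro", parent.gene_id, cid, retro_iv[0], retro_iv[1],
                    strand, parent.n_exons - 1, "none", fused_host, None,
                    "chimeric",
                ))
                _maybe_te(rng, config, contigs, occupied, contig_lengths,
                          repeats, cid, retro_iv, truth[-1])
                continue

        strand = "+" if rng.random() < 0.5 else "-"
        ins_seq = seq if strand == "+" else str(Seq(seq).reverse_complement())
        slot = _find_slot(rng, occupied, contig_lengths, len(ins_seq))
        if slot is None:
            raise ValueError("no intergenic space left for retro event")
        cid, pos = slot
        _write(cid, pos, ins_seq)
        expected = "retropseudogene" if disruption != "none" else (
            "retrogene" if kind == "retrogene" else "intact_unannotated"
        )
        if expected == "retrogene":
            prot = _protein_or_none(seq)
            if prot is None:
                expected = "intact_unannotated"   # mutated copy untranslatable
            else:
                aid = f"{eid}_anno"
                new_genes[aid] = GeneModel(
                    gene_id=aid, transcript_id=f"{aid}.t1", contig_id=cid,
                    strand=strand, exons=[(pos, pos + len(ins_seq))],
                    cds=[(pos, pos + len(ins_seq))], protein=prot,
                )
        truth.append(TruthRecord(
            eid, "retro", parent.gene_id, cid, pos, pos + len(ins_seq),
            strand, parent.n_exons - 1, disruption, None, None, expected,
        ))
        _maybe_te(rng, config, contigs, occupied, contig_lengths, repeats,
                  cid, (pos, pos + len(ins_seq)), truth[-1])

    used_parents = {t.parent_gene_id for t in truth}
    dup_pool = [g for g in parent_pool if g.gene_id not in used_parents] or parent_pool
    for dv in range(config.n_dna_duplications):
        eid = f"dnadup{dv + 1:03d}"
        src = dup_pool[rng.integers(0, len(dup_pool))]
        seg = genome[src.contig_id].sequence[src.start : src.end]
        slot = _find_slot(rng, occupied, contig_lengths, len(seg))
        if slot is None:
            raise ValueError("no intergenic space left for DNA duplication")
        cid, pos = slot
        _write(cid, pos, seg)
        truth.append(TruthRecord(
            eid, "dna_dup", src.gene_id, cid, pos, pos + len(seg),
            src.strand, 0, "none", None, None, "none",
        ))

    mutated = {cid: GenomeSequence(cid, bytes(b).decode()) for cid, b in contigs.items()}
    return mutated, truth, new_genes, repeats


def _protein_or_none(cds: str) -> str | None:
    if len(cds) % 3 or len(cds) < 6:
        return None
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return None if ("*" in prot or not prot.startswith("M")) else prot


def _maybe_te(rng, config, contigs, occupied, contig_lengths, repeats,
              cid, retro_iv, record: TruthRecord) -> None:
    if rng.random() >= config.te_flank_probability:
        return
    classes = list(config.te_class_weights)
    weights = np.array([config.te_class_weights[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=weights / weights.sum())]
    length = int(rng.integers(config.te_length[0], config.te_length[1] + 1))
    gap = int(rng.integers(0, 400))
    side = rng.random() < 0.5
    at = retro_iv[1] + gap if side else retro_iv[0] - gap - length
    if at < 0 or at + length > contig_lengths[cid]:
        return
    lo, hi = at, at + length
    if any(s < hi and lo < e for s, e in occupied[cid]):
        return
    contigs[cid][lo:hi] = _random_seq(rng, length).encode()
    occupied[cid].append((lo, hi))
    repeats.append(RepeatFeature(GenomicInterval(cid, lo, hi), cls))
    record.te_flank = cls


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: Iterable[TruthRecord],
    genes: Mapping[str, GeneModel],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Log-normal FPKM with planted testis bias and parent correlation.

    Retrocopy rows are drawn from a mixture over correlation with the parent
    row (strong ~ 0.9, weak ~ 0.5, independent); a configured fraction of
    retrocopies is expressed in a single tissue only, with testis favoured by
    the bias factor.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    tissues, stages = list(config.tissues), list(config.stages)
    if (config.testis_bias > 0 or config.specific_fraction > 0) and \
            "testis" not in tissues:
        raise ValueError("testis tissue required when testis bias is configured")
    samples = list(itertools.product(tissues, stages))
    S = len(samples)
    retro = [t for t in truth if t.kind == "retro"]
    rows: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    for gid in genes:
        z = rng.standard_normal(S)
        latent[gid] = z
        rows[gid] = np.exp(1.5 + 1.0 * z)
    comp_names = ("strong", "weak", "independent")
    rhos = {"strong": 0.93, "weak": 0.55, "independent": 0.0}
    weights = np.array(config.parent_correlation_weights)
    mixture: dict[str, str] = {}
    specific: dict[str, str] = {}
    tissue_w = np.array([
        config.testis_bias if t == "testis" else 1.0 for t in tissues
    ])
    tissue_w = tissue_w / tissue_w.sum()
    for t in retro:
        comp = comp_names[rng.choice(3, p=weights)]
        mixture[t.event_id] = comp
        rho = rhos[comp]
        zp = latent.get(t.parent_gene_id, rng.standard_normal(S))
        z = rho * zp + np.sqrt(1 - rho ** 2) * rng.standard_normal(S)
        vals = np.exp(0.8 + 1.0 * z)
        if rng.random() < config.specific_fraction:
            tis = tissues[rng.choice(len(tissues), p=tissue_w)]
            mask = np.array([t0 == tis for t0, _ in samples])
            vals = np.where(mask, vals, 0.0)
            specific[t.event_id] = tis
        rows[t.event_id] = vals
    zero_pair = None
    if config.include_zero_pair and retro:
        zero_pair = retro[-1].event_id
        rows[zero_pair] = np.zeros(S)
        specific.pop(zero_pair, None)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(samples, names=["tissue", "stage"])
    return ExpressionMatrix(df), ExpressionTruth(specific, mixture, zero_pair)


# ---------------------------------------------------------------------------
# bundle assembly / fixture emission
# ---------------------------------------------------------------------------

def generate_bundle(config: SimulationConfig, seed: int | None = None,
                    with_expression: bool = True) -> FixtureBundle:
    seed = config.seed if seed is None else seed
    genome, genes = simulate_genome(config, seed)
    genome, truth, new_genes, repeats = plant_retrocopies(genome, genes, config, seed)
    all_genes = {**genes, **new_genes}
    rng = np.random.default_rng(seed + 3)
    regions: list[GenomicInterval] = []
    retro = [t for t in truth if t.kind == "retro"]
    for i in range(config.n_domestication_regions):
        length = int(rng.integers(*config.domestication_region_length))
        if i < config.domestication_overlap_events and retro:
            t = retro[rng.integers(0, len(retro))]
            mid = (t.start + t.end) // 2
            start = max(0, mid - length // 2)
            cid = t.contig_id
        else:
            cid = list(genome)[rng.integers(0, len(genome))]
            start = int(rng.integers(0, max(1, genome[cid].length - length)))
        end = min(genome[cid].length, start + length)
        regions.append(GenomicInterval(cid, start, end, name=f"gross{i + 1}"))
    matrix = etruth = None
    if with_expression:
        matrix, etruth = simulate_expression(truth, genes, config, seed)
    return FixtureBundle(config, seed, genome, all_genes, truth, repeats,
                         sorted(regions, key=lambda r: (r.contig_id, r.start)),
                         matrix, etruth)


TRUTH_COLUMNS = [
    "event_id", "kind", "parent_gene_id", "contig_id", "start", "end",
    "strand", "introns_removed", "disruption", "fused_host", "te_flank",
    "expected_class",
]


def write_truth(truth: Iterable[TruthRecord], path: str | Path,
                seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write("\t".join(str(getattr(t, c) if getattr(t, c) is not None
                                   else "NA") for c in TRUTH_COLUMNS) + "\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(TruthRecord(
            r.event_id, r.kind, r.parent_gene_id, r.contig_id, int(r.start),
            int(r.end), r.strand, int(r.introns_removed), r.disruption,
            None if r.fused_host == "NA" or pd.isna(r.fused_host) else r.fused_host,
            None if r.te_flank == "NA" or pd.isna(r.te_flank) else r.te_flank,
            r.expected_class,
        ))
    return out


def emit_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; re-reading reproduces it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "annotation": out / "annotation.gff3",
        "repeats": out / "repeats.bed",
        "regions": out / "domestication.bed",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.txt",
    }
    write_genome(bundle.genome, paths["genome"])
    write_annotation(bundle.genes.values(), paths["annotation"])
    write_repeat_bed(bundle.repeats, paths["repeats"])
    with open(paths["regions"], "w") as fh:
        for r in bundle.regions:
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.name}\n")
    write_truth(bundle.truth, paths["truth"], seed=bundle.seed)
    if bundle.expression is not None:
        paths["expression"] = out / "expression.tsv"
        write_expression_matrix(bundle.expression, paths["expression"])
    with open(paths["manifest"], "w") as fh:
        fh.write(f"seed={bundle.seed}\n")
        for key, p in sorted(paths.items()):
            if key != "manifest":
                fh.write(f"{key}={p.name}\n")
    return paths
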
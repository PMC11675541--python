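"""Retrocopy identification from protein-to-genome alignment.

The pipeline stages, in order: six-frame alignment of every annotated protein
against the genome; threshold filtering of hits; merging of nearby same-query
fragments; parental-gene assignment against multi-exon-CDS proteins (with
overlapping annotations excluded, so a copy's own annotation can never be its
parent); intron-loss counting and the retention rule (>= 2 lost introns, at
least one > 50 bp); removal of prolific parents (> 10 copies); removal of loci
with multiple highly similar genomic copies (DNA-level duplication); and
classification into retropseudogene / retrogene / chimeric / unannotated.

All numeric thresholds are strict inequalities, matching the wording of the
screening criteria they implement, and live on :class:`CallerParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import molecular_evolution as me
from .alignment_engine import (
    AlignmentParams,
    CodonAlignment,
    GenomeIndex,
    ProteinHit,
    align_protein_to_genome,
    align_protein_to_target,
)
from .io_formats import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    RepeatFeature,
    infer_chromosome_class,
)

log = logging.getLogger("retrokit")


@dataclass
class CallerParams:
    min_identity: float = 0.5        # strict > at the aa level
    min_coverage: float = 0.5
    min_aligned_aa: int = 50
    merge_gap: int = 40              # strict < bp between merged fragments
    retention_min_introns: int = 2   # >= lost introns
    retention_intron_len: int = 50   # strict > bp for at least one lost intron
    fanout_max: int = 10             # strict >: parents above this are purged
    dup_identity: float = 0.8
    dup_coverage: float = 0.8
    dup_min_aa: int = 80
    dup_extra_loci: int = 2          # "multiple" similar copies = >= 2 extras
    stop_horizon: float = 0.9        # premature stop before this span fraction
    end_margin_aa: int = 5           # intron must sit this far inside the span
    insertion_tolerance: float = 0.5  # insertion >= this fraction of intron len
    insertion_window_aa: int = 2
    flank: int = 10_000
    locus_extension: int = 150       # bp of context for parent re-alignment
    alignment: AlignmentParams = field(default_factory=AlignmentParams)


@dataclass
class CandidateLocus:
    contig_id: str
    start: int
    end: int
    strand: str
    query_id: str
    identity: float
    coverage: float
    aligned_length: int
    merged_from: int = 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end, self.strand)


@dataclass
class RetrocopyRecord:
    retro_id: str
    species: str
    contig_id: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    introns_lost: int = 0
    lost_intron_lengths: list[int] = field(default_factory=list)
    disruption: str = "none"
    retro_class: str = "intact_unannotated"
    host_gene_id: str | None = None
    overlaps_annotation: bool = False
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    age_class: str | None = None
    parent_chromosome_class: str = "A"
    locus_chromosome_class: str = "A"
    score: int = 0
    identity: float = 0.0
    # parent-alignment context used by downstream stages
    alignment: ProteinHit | None = None
    target_fwd: str | None = None     # extended locus sequence, forward strand
    target_offset: int = 0            # genomic start of target_fwd
    parent_cds: str | None = None     # parent spliced CDS, reading orientation

    @property
    def max_lost_intron_len(self) -> int:
        return max(self.lost_intron_lengths, default=0)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end, self.strand)

    def locus_sequence(self, genome: Mapping[str, GenomeSequence]) -> str:
        return genome[self.contig_id].sequence[self.start : self.end]


@dataclass
class FlankRepeatProfile:
    retro_id: str
    proportions: dict[str, float]
    flank_span: int


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def filter_candidate_hits(
    hits: Iterable[ProteinHit], params: CallerParams | None = None
) -> list[ProteinHit]:
    """Keep hits with identity > 50%, coverage > 50% and > 50 aligned aa."""
    p = params or CallerParams()
    return [
        h for h in hits
        if h.identity > p.min_identity
        and h.coverage > p.min_coverage
        and h.aligned_length > p.min_aligned_aa
    ]


def merge_candidates(
    hits: Sequence[ProteinHit], max_gap: int | None = None,
    params: CallerParams | None = None,
) -> list[CandidateLocus]:
    """Merge same-contig, same-strand, same-query hits < 40 bp apart.

    Merging is transitive and independent of input order; the merged locus
    spans the union of its fragments.
    """
    p = params or CallerParams()
    gap = p.merge_gap if max_gap is None else max_gap
    groups: dict[tuple[str, str, str], list[ProteinHit]] = {}
    for h in hits:
        groups.setdefault((h.contig_id, h.strand, h.query_id), []).append(h)
    loci: list[CandidateLocus] = []
    for (cid, strand, qid), members in groups.items():
        members = sorted(members, key=lambda h: (h.t_start, h.t_end))
        cluster: list[ProteinHit] = []
        for h in members:
            if cluster and h.t_start - max(x.t_end for x in cluster) < gap:
                cluster.append(h)
            else:
                if cluster:
                    loci.append(_collapse(cluster, cid, strand, qid))
                cluster = [h]
        if cluster:
            loci.append(_collapse(cluster, cid, strand, qid))
    loci.sort(key=lambda l: (l.contig_id, l.start, l.end, l.query_id))
    return loci


def _collapse(cluster: list[ProteinHit], cid: str, strand: str,
              qid: str) -> CandidateLocus:
    total = sum(h.aligned_length for h in cluster)
    ident = sum(h.identity * h.aligned_length for h in cluster) / total
    cov = min(1.0, sum(h.coverage for h in cluster))
    return CandidateLocus(
        contig_id=cid, start=min(h.t_start for h in cluster),
        end=max(h.t_end for h in cluster), strand=strand, query_id=qid,
        identity=ident, coverage=cov, aligned_length=total,
        merged_from=len(cluster),
    )


def assign_parent(
    locus: CandidateLocus,
    genes: Mapping[str, GeneModel],
    genome: Mapping[str, GenomeSequence],
    params: CallerParams | None = None,
) -> tuple[str, ProteinHit, str, int] | None:
    """Best multi-exon parent for a merged locus, or None when none qualifies.

    The pool is restricted to genes whose CDS spans >= 2 segments (the copy of
    a single-exon gene is indistinguishable from a DNA duplicate) and whose
    own annotation does not overlap the locus.  Ties break on score, then
    identity, then alignment length, then gene id.  Returns
    (gene_id, alignment, extended forward target, target genomic offset).
    """
    p = params or CallerParams()
    contig = genome[locus.contig_id]
    off = max(0, locus.start - p.locus_extension)
    target = contig.sequence[off : min(contig.length, locus.end + p.locus_extension)]
    best: tuple | None = None
    for gid in sorted(genes):
        g = genes[gid]
        if len(g.cds) < 2:
            continue
        if g.interval.overlaps(GenomicInterval(locus.contig_id, locus.start,
                                               locus.end)):
            continue
        if len(g.protein) < 20:
            continue
        hits = align_protein_to_target(
            g.protein, target, p.alignment, query_id=gid,
            contig_id=locus.contig_id, strands=locus.strand,
        )
        if not hits:
            continue
        h = hits[0]
        if not (h.identity > p.min_identity and h.coverage > p.min_coverage
                and h.aligned_length > p.min_aligned_aa):
            continue
        key = (-h.score, -h.identity, -h.aligned_length, gid)
        if best is None or key < best[0]:
            best = (key, gid, h)
    if best is None:
        log.info("locus %s:%d-%d dropped: no qualifying multi-exon parent",
                 locus.contig_id, locus.start, locus.end)
        return None
    _, gid, hit = best
    return gid, hit, target, off


def count_lost_introns(
    hit: ProteinHit, parent: GeneModel, params: CallerParams | None = None
) -> tuple[int, list[int]]:
    """Count parent introns absent from the locus alignment.

    An intron is lost when its protein-coordinate position falls well inside
    the aligned span (>= 5 aa from each end) and the alignment shows no target
    insertion of at least half the intron's genomic length near that position.
    """
    p = params or CallerParams()
    introns = parent.cds_intron_protein_positions()
    if not introns:
        raise ValueError(f"{parent.gene_id} has no CDS introns; cannot be a parent")
    insertions = hit.gap_structure()
    lost: list[int] = []
    for pos, ilen in introns:
        if not (hit.q_start + p.end_margin_aa <= pos <= hit.q_end - p.end_margin_aa):
            continue
        retained = any(
            ins_len >= p.insertion_tolerance * ilen
            and abs(q - pos) <= p.insertion_window_aa
            for q, ins_len in insertions
        )
        if not retained:
            lost.append(ilen)
    return len(lost), lost


def apply_retention_rule(
    records: Iterable[RetrocopyRecord], params: CallerParams | None = None
) -> list[RetrocopyRecord]:
    """Keep records that lost >= 2 introns, at least one > 50 bp long."""
    p = params or CallerParams()
    return [
        r for r in records
        if r.introns_lost >= p.retention_min_introns
        and r.max_lost_intron_len > p.retention_intron_len
    ]


def filter_parent_fanout(
    records: Iterable[RetrocopyRecord], max_per_parent: int | None = None,
    params: CallerParams | None = None,
) -> list[RetrocopyRecord]:
    """Purge every record of any parent with more than 10 retrocopies."""
    p = params or CallerParams()
    cap = p.fanout_max if max_per_parent is None else max_per_parent
    counts: dict[str, int] = {}
    records = list(records)
    for r in records:
        counts[r.parent_gene_id] = counts.get(r.parent_gene_id, 0) + 1
    return [r for r in records if counts[r.parent_gene_id] <= cap]


class NucleotideIndex:
    """Exact nt k-mer index for locating near-identical genomic copies."""

    def __init__(self, genome: Mapping[str, GenomeSequence], k: int = 16):
        self.k = k
        self.genome = genome
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for cid, contig in genome.items():
            seq = contig.sequence
            for i in range(0, len(seq) - k + 1):
                self.kmers.setdefault(seq[i : i + k], []).append((cid, i))

    def similar_loci(
        self, seq: str, min_identity: float, min_coverage: float,
        min_aligned_nt: int, exclude: list[GenomicInterval],
    ) -> list[GenomicInterval]:
        """Genomic loci aligning to ``seq`` (either orientation) above the
        thresholds, excluding any locus overlapping the given intervals."""
        import edlib

        hits: list[GenomicInterval] = []
        for query in (seq, str(Seq(seq).reverse_complement())):
            positions: dict[str, list[int]] = {}
            for i in range(0, len(query) - self.k + 1, self.k // 2):
                for cid, pos in self.kmers.get(query[i : i + self.k], ()):
                    positions.setdefault(cid, []).append(pos)
            for cid, plist in positions.items():
                plist.sort()
                windows: list[list[int]] = []
                for pos in plist:
                    if windows and pos - windows[-1][1] <= len(query):
                        windows[-1][1] = pos
                    else:
                        windows.append([pos, pos])
                for a, b in windows:
                    w0 = max(0, a - len(query) // 2)
                    w1 = min(self.genome[cid].length, b + 3 * len(query) // 2)
                    res = edlib.align(query, self.genome[cid].sequence[w0:w1],
                                      mode="HW", task="path")
                    if res["editDistance"] < 0 or not res["locations"]:
                        continue
                    matches = mismatches = 0
                    for n, op in _cigar(res["cigar"]):
                        if op == "=":
                            matches += n
                        elif op == "X":
                            mismatches += n
                    aligned = matches + mismatches
                    if aligned == 0:
                        continue
                    identity = matches / aligned
                    coverage = aligned / len(query)
                    if (identity > min_identity and coverage > min_coverage
                            and aligned > min_aligned_nt):
                        loc0, loc1 = res["locations"][0]
                        iv = GenomicInterval(cid, w0 + loc0, w0 + loc1 + 1)
                        if not any(iv.overlaps(e) for e in exclude):
                            if not any(iv.overlaps(h) for h in hits):
                                hits.append(iv)
        return hits


def _cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def filter_dna_duplicates(
    records: Iterable[RetrocopyRecord],
    genome: Mapping[str, GenomeSequence],
    genes: Mapping[str, GeneModel],
    params: CallerParams | None = None,
    index: NucleotideIndex | None = None,
) -> list[RetrocopyRecord]:
    """Drop records with >= 2 extra highly similar genomic copies.

    A copy counts when it aligns at identity > 80%, coverage > 80% and > 80 aa
    (240 nt) and lies outside both the record itself and its parent gene.
    """
    p = params or CallerParams()
    records = list(records)
    if not records:
        return []
    if index is None:
        index = NucleotideIndex(genome)
    kept = []
    for r in records:
        exclude = [GenomicInterval(r.contig_id, r.start, r.end)]
        if r.parent_gene_id in genes:
            exclude.append(genes[r.parent_gene_id].interval)
        extras = index.similar_loci(
            r.locus_sequence(genome), p.dup_identity, p.dup_coverage,
            3 * p.dup_min_aa, exclude,
        )
        if len(extras) >= p.dup_extra_loci:
            log.info("%s dropped: %d extra similar loci (DNA duplication)",
                     r.retro_id, len(extras))
        else:
            kept.append(r)
    return kept


def detect_disruption(record: RetrocopyRecord,
                      params: CallerParams | None = None) -> str:
    """Frameshift / premature-stop detection on the parent-locus alignment.

    Frameshift: net indel in the aligned span not divisible by 3.  Premature
    stop: an in-frame stop codon before 90% of the aligned parent span.
    """
    p = params or CallerParams()
    hit = record.alignment
    if hit is None:
        return "none"
    if hit.net_frameshift % 3 != 0:
        return "frameshift"
    target_ts = record.target_fwd
    if hit.strand == "-":
        target_ts = str(Seq(record.target_fwd).reverse_complement())
    horizon = hit.q_start + p.stop_horizon * (hit.q_end - hit.q_start)
    for qi, codon in hit.aligned_codons(target_ts):
        if qi >= horizon:
            break
        if "N" not in codon and str(Seq(codon).translate()) == "*":
            return "premature_stop"
    return "none"


def classify_retrocopy(
    record: RetrocopyRecord, genes: Mapping[str, GeneModel],
    params: CallerParams | None = None,
) -> str:
    """retropseudogene if disrupted; else chimeric / retrogene by the exon
    count of an overlapping annotated transcript; else intact_unannotated."""
    record.disruption = detect_disruption(record, params)
    iv = GenomicInterval(record.contig_id, record.start, record.end)
    overlapping = [
        g for g in genes.values()
        if g.gene_id != record.parent_gene_id and g.interval.overlaps(iv)
    ]
    record.overlaps_annotation = bool(overlapping)
    if overlapping:
        host = max(
            overlapping,
            key=lambda g: min(g.end, record.end) - max(g.start, record.start),
        )
        record.host_gene_id = host.gene_id
    if record.disruption != "none":
        record.retro_class = "retropseudogene"
    elif overlapping:
        host = genes[record.host_gene_id]
        record.retro_class = "chimeric" if host.n_exons >= 2 else "retrogene"
    else:
        record.retro_class = "intact_unannotated"
    return record.retro_class


def _dedup(records: list[RetrocopyRecord]) -> list[RetrocopyRecord]:
    """Collapse overlapping loci found via different query proteins."""
    out: list[RetrocopyRecord] = []
    by_contig: dict[str, list[RetrocopyRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    for cid, rs in sorted(by_contig.items()):
        rs.sort(key=lambda r: (r.start, r.end))
        cluster: list[RetrocopyRecord] = []
        for r in rs:
            if cluster and r.start < max(x.end for x in cluster):
                cluster.append(r)
            else:
                if cluster:
                    out.append(_best(cluster))
                cluster = [r]
        if cluster:
            out.append(_best(cluster))
    return out


def _best(cluster: list[RetrocopyRecord]) -> RetrocopyRecord:
    return min(cluster, key=lambda r: (-r.score, -(r.end - r.start),
                                       r.start, r.parent_gene_id))


def retro_cds_alignment(record: RetrocopyRecord) -> CodonAlignment | None:
    """Codon alignment of the locus against the parent CDS, built from the
    in-frame columns of the parent-locus alignment."""
    hit = record.alignment
    if hit is None or record.target_fwd is None or record.parent_cds is None:
        return None
    target_ts = record.target_fwd
    if hit.strand == "-":
        target_ts = str(Seq(record.target_fwd).reverse_complement())
    return _codon_alignment_from_hit(hit, target_ts, record.parent_cds)


def _codon_alignment_from_hit(hit: ProteinHit, target_ts: str,
                              parent_cds: str) -> CodonAlignment | None:
    pa, pb = [], []
    for qi, codon in hit.aligned_codons(target_ts):
        pc = parent_cds[3 * qi : 3 * qi + 3]
        if len(pc) == 3 and len(codon) == 3:
            pa.append(pc)
            pb.append(codon)
    if not pa:
        return None
    return CodonAlignment("".join(pa), "".join(pb))


def call_retrocopies(
    genome: Mapping[str, GenomeSequence],
    genes: Mapping[str, GeneModel],
    params: CallerParams | None = None,
    species: str = "synthetic",
    compute_kaks: bool = True,
) -> list[RetrocopyRecord]:
    """Run the full identification pipeline; deterministic given its inputs."""
    p = params or CallerParams()
    index = GenomeIndex(
        {cid: c for cid, c in genome.items()
         if c.length > p.alignment.full_dp_threshold},
        k=p.alignment.seed_k,
    )
    all_hits: list[ProteinHit] = []
    for gid in sorted(genes):
        g = genes[gid]
        if len(g.protein) < 20:
            continue
        try:
            hits = align_protein_to_genome(g.protein, genome, p.alignment,
                                           query_id=gid, index=index)
        except ValueError as exc:
            raise RuntimeError(f"alignment stage failed for {gid}: {exc}")
        all_hits.extend(hits)
    log.info("alignment: %d raw hits", len(all_hits))

    kept = filter_candidate_hits(all_hits, p)
    loci = merge_candidates(kept, params=p)
    log.info("filter+merge: %d loci", len(loci))

    records: list[RetrocopyRecord] = []
    for locus in loci:
        assigned = assign_parent(locus, genes, genome, p)
        if assigned is None:
            continue
        gid, hit, target, off = assigned
        parent = genes[gid]
        start, end = off + hit.t_start, off + hit.t_end
        rec = RetrocopyRecord(
            retro_id="", species=species, contig_id=locus.contig_id,
            start=start, end=end, strand=hit.strand, parent_gene_id=gid,
            score=hit.score, identity=hit.identity,
            alignment=hit, target_fwd=target, target_offset=off,
            parent_chromosome_class=parent.chromosome_class,
            locus_chromosome_class=infer_chromosome_class(locus.contig_id),
            parent_cds=parent.spliced_cds(genome),
        )
        try:
            n, lengths = count_lost_introns(hit, parent, p)
        except ValueError:
            continue
        rec.introns_lost, rec.lost_intron_lengths = n, lengths
        records.append(rec)

    records = _dedup(records)
    records = apply_retention_rule(records, p)
    log.info("retention: %d records", len(records))
    records = filter_parent_fanout(records, params=p)
    records = filter_dna_duplicates(records, genome, genes, p)
    records.sort(key=lambda r: (r.contig_id, r.start))
    for i, rec in enumerate(records, 1):
        rec.retro_id = f"RC{i:04d}"
        classify_retrocopy(rec, genes, p)
        if compute_kaks:
            ca = retro_cds_alignment(rec)
            if ca is not None:
                try:
                    res = me.ng86_kaks(ca)
                except ValueError:
                    res = None
                if res is not None:
                    rec.ka, rec.ks, rec.ka_ks = res.ka, res.ks, res.ratio
                    rec.age_class = me.classify_age(rec.ks)
    log.info("final catalog: %d records", len(records))
    return records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else float("nan")


def summary_from_counts(n_retrocopies: int, n_parents: int, n_intact: int,
                        n_retrogene: int, n_chimeric: int) -> dict[str, float]:
    """Catalog arithmetic from plain counts (per-parent ratio, class shares)."""
    return {
        "n_retrocopies": n_retrocopies,
        "n_parents": n_parents,
        "retrocopies_per_parent": round(n_retrocopies / n_parents, 2),
        "intact_pct": _pct(n_intact, n_retrocopies),
        "retropseudogene_pct": _pct(n_retrocopies - n_intact, n_retrocopies),
        "retrogene_chimeric_pct_of_intact": _pct(n_retrogene + n_chimeric,
                                                 n_intact),
    }


def summarize_catalog(records: Sequence[RetrocopyRecord]) -> dict:
    """Counts per class plus the derived shares, on called records."""
    by_class: dict[str, int] = {}
    by_chrom: dict[str, int] = {}
    for r in records:
        by_class[r.retro_class] = by_class.get(r.retro_class, 0) + 1
        by_chrom[r.locus_chromosome_class] = (
            by_chrom.get(r.locus_chromosome_class, 0) + 1
        )
    n = len(records)
    intact = n - by_class.get("retropseudogene", 0)
    parents = {r.parent_gene_id for r in records}
    out = summary_from_counts(
        n, max(len(parents), 1), intact,
        by_class.get("retrogene", 0), by_class.get("chimeric", 0),
    )
    out["class_counts"] = by_class
    out["chromosome_class_counts"] = by_chrom
    return out


def flank_repeat_profile(
    record: RetrocopyRecord,
    repeats: Sequence[RepeatFeature],
    flank: int | None = None,
    contig_length: int | None = None,
    params: CallerParams | None = None,
) -> FlankRepeatProfile:
    """Per-class base-coverage proportions within +/- 10 kb of the locus.

    Flanks are clipped at contig bounds; the denominator is the clipped span.
    """
    p = params or CallerParams()
    f = p.flank if flank is None else flank
    up0, up1 = max(0, record.start - f), record.start
    dn0 = record.end
    dn1 = record.end + f if contig_length is None else min(record.end + f,
                                                           contig_length)
    span = (up1 - up0) + (dn1 - dn0)
    props: dict[str, float] = {}
    for cls in ("SINE", "LINE", "LTR", "DNA", "other"):
        ivs = []
        for rep in repeats:
            if rep.repeat_class != cls or rep.interval.contig_id != record.contig_id:
                continue
            for a, b in ((up0, up1), (dn0, dn1)):
                s, e = max(rep.interval.start, a), min(rep.interval.end, b)
                if s < e:
                    ivs.append((s, e))
        covered = 0
        last_end = -1
        for s, e in sorted(ivs):   # union, so stacked repeats count once
            s = max(s, last_end)
            if e > s:
                covered += e - s
                last_end = e
        props[cls] = covered / span if span else 0.0
    return FlankRepeatProfile(record.retro_id, props, span)
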
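"""Domestication-region overlap, lineage-specific retrocopies, and the
end-to-end pipeline orchestration.

Candidate domestication regions (selective-sweep intervals distinguishing the
domestic from the wild lineage) are inputs; a called retrocopy is reported
when its locus intersects a region by at least one base.  A retrocopy is
lineage-specific (post-domestication) when no locus in the comparison genome
aligns to it at the orthology thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    RepeatFeature,
    read_bed_regions,
    read_expression_matrix,
    read_genome,
    read_annotation,
    read_repeat_annotation,
    setup_logging,
)
from .retrocopy_caller import (
    CallerParams,
    NucleotideIndex,
    RetrocopyRecord,
    call_retrocopies,
    flank_repeat_profile,
    summarize_catalog,
)

log = logging.getLogger("retrokit")


@dataclass
class DomesticationReport:
    overlapping: list[tuple[str, list[str]]]    # (retro_id, region names)
    lineage_specific: list[str]
    annotations: dict[str, dict]                # retro_id -> class/kaks/expr


def overlap_domestication(
    records: Sequence[RetrocopyRecord],
    regions: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[tuple[RetrocopyRecord, list[GenomicInterval]]]:
    """Records whose locus intersects any region by >= min_overlap_bp."""
    out = []
    for r in records:
        hits = [
            g for g in regions
            if g.contig_id == r.contig_id
            and min(g.end, r.end) - max(g.start, r.start) >= min_overlap_bp
        ]
        if hits:
            out.append((r, hits))
    return out


def lineage_specific(
    records: Sequence[RetrocopyRecord],
    genome: Mapping[str, GenomeSequence],
    other_genome: Mapping[str, GenomeSequence],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    min_length: int = 50,
    expressed_ids: set[str] | None = None,
    index: NucleotideIndex | None = None,
) -> list[RetrocopyRecord]:
    """Records with no counterpart locus in the comparison genome.

    A counterpart is any alignment at identity > 0.8, coverage > 0.8 and
    > 50 bp; records with one are orthologous to the other lineage and thus
    predate the split.  ``expressed_ids`` optionally restricts the report to
    expressed retrocopies.
    """
    if index is None:
        index = NucleotideIndex(other_genome)
    out = []
    for r in records:
        if expressed_ids is not None and r.retro_id not in expressed_ids:
            continue
        hits = index.similar_loci(
            r.locus_sequence(genome), min_identity, min_coverage,
            min_length, exclude=[],
        )
        if not hits:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    genome: str | Path = ""
    annotation: str | Path = ""
    repeats: str | Path | None = None
    regions: str | Path | None = None
    expression: str | Path | None = None
    pairs: str | Path | None = None             # optional retro/parent pairs TSV
    other_genome: str | Path | None = None      # comparison (wild) genome
    out_dir: str | Path = "retrokit_out"
    species: str = "sample"
    seed: int = 0
    caller: CallerParams = field(default_factory=CallerParams)
    expressed_threshold: float = 0.0


def run_full_pipeline(config: PipelineConfig) -> dict:
    """call -> evolve -> express -> domesticate, with per-stage logging.

    Stages whose inputs are absent are skipped with a warning.  Returns a
    manifest of outputs; all files are TSV/JSON under ``config.out_dir``.
    """
    from . import expression_analysis as ea

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": {}, "seed": config.seed}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- call ---------------------------------------------------------
    try:
        genome = read_genome(config.genome)
        genes = read_annotation(config.annotation, genome)
        records = call_retrocopies(genome, genes, config.caller,
                                   species=config.species)
    except Exception as exc:
        fail("call", exc)
    manifest["stages"]["call"] = {"n_records": len(records)}
    records_path = out_dir / "records.tsv"
    write_records(records, records_path)
    manifest["outputs"]["records"] = str(records_path)
    bed_path = out_dir / "records.bed"
    with open(bed_path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.retro_id}\t"
                     f"{r.score}\t{r.strand}\n")
    manifest["outputs"]["records_bed"] = str(bed_path)
    summary = summarize_catalog(records)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str))
    manifest["outputs"]["summary"] = str(summary_path)

    # --- repeats ------------------------------------------------------
    if config.repeats:
        try:
            repeats = read_repeat_annotation(config.repeats)
            profiles = [
                flank_repeat_profile(r, repeats, params=config.caller,
                                     contig_length=genome[r.contig_id].length)
                for r in records
            ]
        except Exception as exc:
            fail("repeat_profile", exc)
        prof_path = out_dir / "flank_repeats.tsv"
        with open(prof_path, "w") as fh:
            fh.write("retro_id\tSINE\tLINE\tLTR\tDNA\tother\tflank_span\n")
            for p in profiles:
                fh.write(p.retro_id + "\t" + "\t".join(
                    f"{p.proportions[c]:.4f}"
                    for c in ("SINE", "LINE", "LTR", "DNA", "other"))
                    + f"\t{p.flank_span}\n")
        manifest["outputs"]["flank_repeats"] = str(prof_path)
        manifest["stages"]["repeat_profile"] = {"n": len(profiles)}
    else:
        log.warning("repeat stage skipped: no repeat annotation provided")

    # --- express ------------------------------------------------------
    if config.expression:
        try:
            matrix = read_expression_matrix(config.expression)
            known = [r.retro_id for r in records
                     if r.retro_id in matrix.values.index]
            pairs = [(r.retro_id, r.parent_gene_id) for r in records
                     if r.retro_id in matrix.values.index
                     and r.parent_gene_id in matrix.values.index]
            correlations = ea.pair_correlations(matrix, pairs) if pairs else []
        except Exception as exc:
            fail("express", exc)
        corr_path = out_dir / "correlations.tsv"
        with open(corr_path, "w") as fh:
            fh.write("retro_id\tparent_id\tR\tp\tq\tcategory\tn\n")
            for c in correlations:
                fh.write(f"{c.retro_id}\t{c.parent_id}\t{c.r:.4f}\t{c.p:.3g}\t"
                         f"{c.q:.3g}\t{c.category}\t{c.n_samples}\n")
        manifest["outputs"]["correlations"] = str(corr_path)
        manifest["stages"]["express"] = {"n_pairs": len(correlations)}
        expressed_ids = {
            r.retro_id for r in records
            if r.retro_id in matrix.values.index
            and (matrix.row(r.retro_id) > config.expressed_threshold).any()
        }
    else:
        matrix = None
        expressed_ids = None
        log.warning("express stage skipped: no expression matrix provided")

    # --- domesticate --------------------------------------------------
    report = None
    if config.regions:
        try:
            regions = read_bed_regions(config.regions)
            overlaps = overlap_domestication(records, regions)
        except Exception as exc:
            fail("domesticate", exc)
        specific_ids: list[str] = []
        if config.other_genome:
            other = read_genome(config.other_genome)
            specific = lineage_specific(records, genome, other,
                                        expressed_ids=expressed_ids)
            specific_ids = [r.retro_id for r in specific]
        report = DomesticationReport(
            overlapping=[(r.retro_id, [g.name or f"{g.contig_id}:{g.start}"
                                       for g in gs]) for r, gs in overlaps],
            lineage_specific=specific_ids,
            annotations={
                r.retro_id: {
                    "class": r.retro_class, "ka_ks": r.ka_ks,
                    "host_gene": r.host_gene_id,
                    "expressed": (expressed_ids is not None
                                  and r.retro_id in expressed_ids),
                }
                for r, _ in overlaps
            },
        )
        dom_path = out_dir / "domestication.json"
        dom_path.write_text(json.dumps({
            "overlapping": report.overlapping,
            "lineage_specific": report.lineage_specific,
            "annotations": report.annotations,
        }, indent=2, default=str))
        manifest["outputs"]["domestication"] = str(dom_path)
        manifest["stages"]["domesticate"] = {
            "n_overlapping": len(report.overlapping),
            "n_lineage_specific": len(report.lineage_specific),
        }
    else:
        log.warning("domestication stage skipped: no regions provided")

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


RECORD_COLUMNS = [
    "retro_id", "species", "contig_id", "start", "end", "strand",
    "parent_gene_id", "introns_lost", "max_lost_intron_len", "disruption",
    "retro_class", "host_gene_id", "overlaps_annotation", "ka", "ks",
    "ka_ks", "age_class", "parent_chromosome_class", "locus_chromosome_class",
    "score", "identity",
]


def write_records(records: Sequence[RetrocopyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RECORD_COLUMNS) + "\n")
        for r in records:
            vals = []
            for c in RECORD_COLUMNS:
                v = getattr(r, c)
                if v is None:
                    vals.append("NA")
                elif isinstance(v, float):
                    vals.append(f"{v:.4f}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
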
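"""Readers and writers for the standard formats the pipeline touches.

The coordinate contract for the whole package is established here: every
in-memory interval is 0-based half-open ``[start, end)``.  GFF3 input/output
(1-based inclusive) is converted at the boundary, BED is consumed as-is.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger("retrokit")

VALID_NT = set("ACGTN")
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "other")


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeSequence:
    """One contig: uppercase nucleotides over {A,C,G,T,N}.

    ``soft_masked`` preserves lowercase (repeat-masked) input positions as a
    boolean array; ``None`` when the input carried no masking.
    """

    contig_id: str
    sequence: str
    soft_masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise FormatError(
                f"contig {self.contig_id}: unsupported characters {sorted(bad)!r} "
                "(only A/C/G/T/N allowed)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene reduced to its single longest transcript.

    Exons and CDS intervals are 0-based half-open on the forward strand and
    sorted by genomic start regardless of transcript strand.  ``protein`` is
    the translation of the spliced, phase-trimmed CDS without the terminal
    stop.
    """

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein: str
    chromosome_class: str = "A"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} {b}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end, self.strand)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def spliced_cds(self, genome: Mapping[str, GenomeSequence]) -> str:
        """Spliced CDS in reading orientation (5'->3' of the mRNA)."""
        seq = genome[self.contig_id].sequence
        s = "".join(seq[a:b] for a, b in self.cds)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def intron_lengths(self) -> list[int]:
        """Genomic intron lengths in transcript order (5'->3')."""
        gaps = [b[0] - a[1] for a, b in zip(self.exons, self.exons[1:])]
        return gaps[::-1] if self.strand == "-" else gaps

    def cds_intron_protein_positions(self) -> list[tuple[float, int]]:
        """(protein position in aa, intron genomic length) for each intron
        interrupting the CDS, in transcript order.

        The protein position is the cumulative spliced-CDS length upstream of
        the intron divided by 3 (fractional when the intron splits a codon).
        """
        cds = self.cds if self.strand == "+" else self.cds[::-1]
        lengths = [e - s for s, e in cds]
        gaps = []
        for a, b in zip(cds, cds[1:]):
            gaps.append(abs(b[0] - a[1]) if self.strand == "+" else abs(a[0] - b[1]))
        out = []
        cum = 0
        for seg_len, gap in zip(lengths, gaps):
            cum += seg_len
            out.append((cum / 3.0, gap))
        return out


@dataclass(frozen=True)
class RepeatFeature:
    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


@dataclass
class ExpressionMatrix:
    """FPKM matrix: rows are gene/retrocopy ids, columns (tissue, stage)."""

    values: pd.DataFrame  # columns: MultiIndex (tissue, stage)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise FormatError("expression matrix contains negative FPKM values")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicated row ids: {dup}")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(1)))

    def row(self, rid: str) -> np.ndarray:
        return self.values.loc[rid].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Parse a FASTA file into ``{contig_id: GenomeSequence}``.

    Lowercase (soft-masked) bases are uppercased with the mask recorded per
    position.  Duplicate ids and non-ACGTN characters are rejected.
    """
    path = Path(path)
    genome: dict[str, GenomeSequence] = {}
    cur_id: str | None = None
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if cur_id is None:
            return
        raw = "".join(chunks)
        upper = raw.upper()
        masked = None
        if raw != upper:
            masked = np.frombuffer(raw.encode(), dtype=np.uint8) >= ord("a")
        try:
            genome[cur_id] = GenomeSequence(cur_id, upper, masked)
        except FormatError as exc:
            raise FormatError(f"{path} (record ending line {line_no}): {exc}")

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(ln)
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise FormatError(f"{path}:{ln}: empty FASTA header")
                if cur_id in genome:
                    raise FormatError(f"{path}:{ln}: duplicate contig id {cur_id!r}")
                chunks = []
            else:
                if cur_id is None:
                    raise FormatError(f"{path}:{ln}: sequence before first header")
                chunks.append(line)
        _flush(ln if chunks or cur_id else 0)
    return genome


def write_genome(genome: Mapping[str, GenomeSequence], path: str | Path,
                 width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in genome.values():
            fh.write(f">{contig.contig_id}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def infer_chromosome_class(contig_id: str) -> str:
    """Default contig -> {Z, A, unplaced} mapping by naming convention."""
    if re.fullmatch(r"(chr)?Z", contig_id, flags=re.IGNORECASE):
        return "Z"
    if re.fullmatch(r"(chr)?\d+", contig_id, flags=re.IGNORECASE):
        return "A"
    return "unplaced"


def _translate_cds(spliced: str, phase: int) -> str | None:
    """Translate a phase-trimmed spliced CDS; None when not clean."""
    s = spliced[phase:]
    if len(s) < 6 or len(s) % 3:
        return None
    prot = str(Seq(s).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        return None
    return prot


def read_annotation(
    path: str | Path,
    genome: Mapping[str, GenomeSequence],
    chromosome_class: Mapping[str, str] | None = None,
) -> dict[str, GeneModel]:
    """Parse GFF3 gene models, keeping one longest transcript per gene.

    "Longest" means longest CDS in nucleotides; ties break toward the
    lexicographically smallest transcript id.  Genes whose CDS is not a clean
    multiple of three after phase trimming, or whose translation contains an
    internal stop, are skipped with a warning.  Exons outside their contig are
    an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        best_key: tuple[int, str] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds_feats = sorted(
                db.children(mrna, featuretype="CDS"), key=lambda f: f.start
            )
            if not exons or not cds_feats:
                continue
            cds = [(f.start - 1, f.end) for f in cds_feats]
            contig = gene.seqid
            if contig not in genome:
                raise FormatError(f"{path}: contig {contig!r} absent from genome")
            clen = genome[contig].length
            for s, e in exons:
                if s < 0 or e > clen:
                    raise FormatError(
                        f"{path}: exon {s}-{e} of {mrna.id} outside contig {contig}"
                    )
            first = cds_feats[0] if gene.strand == "+" else cds_feats[-1]
            phase = int(first.frame) if first.frame in ("0", "1", "2") else 0
            spliced = "".join(genome[contig].sequence[s:e] for s, e in sorted(cds))
            if gene.strand == "-":
                spliced = str(Seq(spliced).reverse_complement())
            prot = _translate_cds(spliced, phase)
            if prot is None:
                log.warning(
                    "skipping transcript %s of %s: CDS not cleanly translatable",
                    mrna.id, gene.id,
                )
                continue
            key = (-sum(e - s for s, e in cds), mrna.id)
            if best_key is None or key < best_key:
                best_key = key
                cls = (
                    chromosome_class.get(contig, infer_chromosome_class(contig))
                    if chromosome_class is not None
                    else infer_chromosome_class(contig)
                )
                best = GeneModel(
                    gene_id=gene.id, transcript_id=mrna.id, contig_id=contig,
                    strand=gene.strand, exons=sorted(exons), cds=sorted(cds),
                    protein=prot, chromosome_class=cls,
                )
        if best is not None:
            out[best.gene_id] = best
        else:
            log.warning("gene %s has no usable transcript", gene.id)
    return out


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS GFF3 (coordinates back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            c, st = g.contig_id, g.strand
            fh.write(f"{c}\tretrokit\tgene\t{g.start + 1}\t{g.end}\t.\t{st}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{c}\tretrokit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{st}\t.\t"
                     f"ID={g.transcript_id};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{c}\tretrokit\texon\t{s + 1}\t{e}\t.\t{st}\t.\t"
                         f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}\n")
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(f"{c}\tretrokit\tCDS\t{s + 1}\t{e}\t.\t{st}\t0\t"
                         f"ID={g.transcript_id}.cds{i};Parent={g.transcript_id}\n")


# ---------------------------------------------------------------------------
# BED / RepeatMasker
# ---------------------------------------------------------------------------

def read_bed_regions(path: str | Path) -> list[GenomicInterval]:
    """3+ column BED (0-based half-open), validated and sorted."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            contig, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinates")
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{ln}: invalid interval {start}-{end}")
            name = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(contig, start, end, name=name))
    return sorted(out, key=lambda iv: (iv.contig_id, iv.start, iv.end))


def normalize_repeat_class(label: str) -> str:
    """Map a RepeatMasker class/family label onto the closed vocabulary."""
    head = label.split("/")[0].strip()
    for cls in ("SINE", "LINE", "LTR", "DNA"):
        if head.upper().startswith(cls):
            return cls
    return "other"


def read_repeat_annotation(path: str | Path) -> list[RepeatFeature]:
    """Parse RepeatMasker ``.out`` tables or 4-column BED with a class column.

    The dialect is sniffed per file: RepeatMasker tables carry the standard
    score/divergence header and whitespace-separated columns with the repeat
    class in column 11; BED is tab-separated with the class label in column 4.
    Coordinates in ``.out`` are 1-based inclusive and converted.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    body = [l for l in text if l.strip()]
    is_out = any(l.lstrip().lower().startswith(("sw", "score")) for l in body[:3]) or (
        body and not body[0].startswith(("#", "track")) and "\t" not in body[0]
    )
    feats: list[RepeatFeature] = []
    if is_out:
        for ln, line in enumerate(text, 1):
            s = line.split()
            if not s or s[0].lower() in ("sw", "score") or not s[0][0].isdigit():
                continue
            if len(s) < 11:
                raise FormatError(f"{path}:{ln}: expected >=11 RepeatMasker columns")
            contig, start, end, cls = s[4], int(s[5]) - 1, int(s[6]), s[10]
            feats.append(
                RepeatFeature(GenomicInterval(contig, start, end),
                              normalize_repeat_class(cls))
            )
    else:
        for ln, line in enumerate(text, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 BED columns with class")
            feats.append(
                RepeatFeature(GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                              normalize_repeat_class(parts[3]))
            )
    return feats


def write_repeat_bed(feats: Iterable[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in feats:
            iv = f.interval
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{f.repeat_class}\n")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV whose header encodes tissue__stage."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise FormatError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    cols = []
    for c in df.columns:
        if "__" not in c:
            raise FormatError(f"{path}: column {c!r} is not of the form tissue__stage")
        tissue, stage = c.split("__", 1)
        cols.append((tissue, stage))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["tissue", "stage"])
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative FPKM value present")
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.columns = [f"{t}__{s}" for t, s in df.columns]
    df.index.name = "id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Global run settings mirrored by every CLI flag and the config file."""

    seed: int = 0
    out_dir: str = "retrokit_out"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """key=value config file; unknown keys are kept in ``extra``."""
        cfg = cls()
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{ln}: expected key=value")
                k, v = (x.strip() for x in line.split("=", 1))
                if k == "seed":
                    cfg.seed = int(v)
                elif k == "out_dir":
                    cfg.out_dir = v
                elif k == "log_level":
                    cfg.log_level = v
                else:
                    cfg.extra[k] = v
        return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
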
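"""Alignment primitives for retrocopy calling.

The centrepiece is a local, frameshift-tolerant alignment of a protein query
against genomic DNA: three reading frames per strand are searched in a single
dynamic program whose match step consumes 3 nt, with 2-nt and 4-nt "frameshift"
consumes allowed at a fixed penalty.  Because retrocopies are intronless, no
spliced alignment is attempted; a retained intron simply appears as a long
target insertion.

Scoring transliterates classic translated-search settings: BLOSUM62, gap
open 11 + extend 2 (so a gap of length k costs 11 + 2k), frameshift 15.
Query-side gaps are costed per amino acid, target-side insertions per
nucleotide.  For genome-scale targets an exact 5-mer peptide seed index
restricts the DP to candidate windows; small targets are solved exhaustively,
which is what the brute-force oracle tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .io_formats import GenomeSequence

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
NEG = -(10 ** 8)

# ops in traceback columns
OP_MATCH = 0   # consumes 1 aa + nlen nt (nlen == 3, or 2/4 across a frameshift)
OP_DEL = 1     # query residue deleted (no nt consumed)
OP_INS = 2     # target nucleotides inserted (no query consumed)


@dataclass
class AlignmentParams:
    gap_open: int = 11
    gap_extend: int = 2
    frameshift: int = 15
    min_score: int = 50
    full_dp_threshold: int = 10_000   # targets up to this length skip seeding
    seed_k: int = 5
    seed_window_pad: int = 200        # nt added beyond the DP-reachable span

    @property
    def open_cost(self) -> int:
        # first gapped position pays open + extend, matching cost(k) = open + k*ext
        return self.gap_open + self.gap_extend


@lru_cache(maxsize=1)
def _tables() -> tuple[np.ndarray, np.ndarray]:
    """(aa substitution matrix int16[A,A], codon-code -> aa index int16[125])."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    sub = np.zeros((n, n), dtype=np.int16)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            sub[i, j] = int(blosum[a][b])
    codon_aa = np.full(125, _AA_INDEX["X"], dtype=np.int16)
    for c0, n0 in enumerate("ACGT"):
        for c1, n1 in enumerate("ACGT"):
            for c2, n2 in enumerate("ACGT"):
                aa = str(Seq(n0 + n1 + n2).translate())
                codon_aa[c0 * 25 + c1 * 5 + c2] = _AA_INDEX[aa]
    return sub, codon_aa


def encode_protein(protein: str) -> np.ndarray:
    out = np.empty(len(protein), dtype=np.int16)
    for i, a in enumerate(protein):
        if a not in _AA_INDEX or a in "BZ*":
            raise ValueError(f"non-standard residue {a!r} at position {i}")
        out[i] = _AA_INDEX[a]
    return out


_NT_TABLE = np.full(256, 4, dtype=np.int8)
for _c, _i in _NT_INDEX.items():
    _NT_TABLE[ord(_c)] = _i
    _NT_TABLE[ord(_c.lower())] = _i


def encode_nt(seq: str) -> np.ndarray:
    return _NT_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=False)
def _fill(q, t, sub, codon_aa, open_cost, ext, fs):  # pragma: no cover - jit
    m, n = q.shape[0], t.shape[0]
    M = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    PM = np.zeros((m + 1, n + 1), dtype=np.int8)
    PX = np.zeros((m + 1, n + 1), dtype=np.int8)
    PY = np.zeros((m + 1, n + 1), dtype=np.int8)
    xi = sub.shape[0] - 2  # 'X' row index in AA_ALPHABET
    for i in range(1, m + 1):
        qa = q[i - 1]
        for j in range(1, n + 1):
            best = NEG
            ptr = 0
            # 3-nt consume
            if j >= 3:
                code = t[j - 3] * 25 + t[j - 2] * 5 + t[j - 1]
                s = sub[qa, codon_aa[code]]
                pm, px, py = M[i - 1, j - 3], X[i - 1, j - 3], Y[i - 1, j - 3]
                if 0 >= pm and 0 >= px and 0 >= py:
                    best, ptr = s, 4
                elif pm >= px and pm >= py:
                    best, ptr = pm + s, 1
                elif px >= py:
                    best, ptr = px + s, 2
                else:
                    best, ptr = py + s, 3
            # 2-nt consume (frameshift); residue scored against X
            if j >= 2:
                s = sub[qa, xi] - fs
                pm, px, py = M[i - 1, j - 2], X[i - 1, j - 2], Y[i - 1, j - 2]
                pbest, pptr = 0, 8
                if pm >= px and pm >= py and pm > 0:
                    pbest, pptr = pm, 5
                elif px >= py and px > 0:
                    pbest, pptr = px, 6
                elif py > 0:
                    pbest, pptr = py, 7
                cand = pbest + s
                if cand > best:
                    best, ptr = cand, pptr
            # 4-nt consume (frameshift); scored on the last 3 nt
            if j >= 4:
                code = t[j - 3] * 25 + t[j - 2] * 5 + t[j - 1]
                s = sub[qa, codon_aa[code]] - fs
                pm, px, py = M[i - 1, j - 4], X[i - 1, j - 4], Y[i - 1, j - 4]
                pbest, pptr = 0, 12
                if pm >= px and pm >= py and pm > 0:
                    pbest, pptr = pm, 9
                elif px >= py and px > 0:
                    pbest, pptr = px, 10
                elif py > 0:
                    pbest, pptr = py, 11
                cand = pbest + s
                if cand > best:
                    best, ptr = cand, pptr
            M[i, j] = best
            PM[i, j] = ptr
            # query residue deletion (no nt consumed)
            a = M[i - 1, j] - open_cost
            b = X[i - 1, j] - ext
            if a >= b:
                X[i, j], PX[i, j] = a, 0
            else:
                X[i, j], PX[i, j] = b, 1
            # target insertion (per nt)
            a = M[i, j - 1] - open_cost
            b = Y[i, j - 1] - ext
            if a >= b:
                Y[i, j], PY[i, j] = a, 0
            else:
                Y[i, j], PY[i, j] = b, 1
    return M, X, Y, PM, PX, PY


@dataclass
class RawHit:
    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    # columns: (op, q_index, t_start, nt_len); q_index/-1, coords in target space
    columns: list[tuple[int, int, int, int]] = field(default_factory=list)


def _traceback(i, j, PM, PX, PY) -> tuple[int, int, list]:
    cols: list[tuple[int, int, int, int]] = []
    state = 0  # M
    while True:
        if state == 0:
            ptr = PM[i, j]
            if ptr == 0:
                break
            # decode: 1-4 => 3nt, 5-8 => 2nt, 9-12 => 4nt; within group: M,X,Y,start
            if ptr <= 4:
                nlen, prev_state = 3, ptr - 1
            elif ptr <= 8:
                nlen, prev_state = 2, ptr - 5
            else:
                nlen, prev_state = 4, ptr - 9
            cols.append((OP_MATCH, i - 1, j - nlen, nlen))
            i, j = i - 1, j - nlen
            if prev_state == 3:
                break
            state = prev_state
        elif state == 1:
            ptr = PX[i, j]
            cols.append((OP_DEL, i - 1, j, 0))
            i -= 1
            state = 0 if ptr == 0 else 1
        else:
            ptr = PY[i, j]
            cols.append((OP_INS, -1, j - 1, 1))
            j -= 1
            state = 0 if ptr == 0 else 2
    cols.reverse()
    # merge consecutive insertion columns into runs
    merged: list[tuple[int, int, int, int]] = []
    for c in cols:
        if merged and c[0] == OP_INS and merged[-1][0] == OP_INS:
            op, qi, ts, ln = merged[-1]
            merged[-1] = (op, qi, ts, ln + 1)
        else:
            merged.append(c)
    return i, j, merged


def _dp_hits(q: np.ndarray, t: np.ndarray, params: AlignmentParams,
             t_offset: int = 0) -> list[RawHit]:
    """All local hits with score >= min_score, greedily non-overlapping in t."""
    if q.shape[0] == 0 or t.shape[0] == 0:
        return []
    sub, codon_aa = _tables()
    M, X, Y, PM, PX, PY = _fill(
        q, t.astype(np.int16), sub, codon_aa,
        params.open_cost, params.gap_extend, params.frameshift,
    )
    score = int(M.max())
    if score < params.min_score:
        return []
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    qi0, tj0, cols = _traceback(int(i), int(j), PM, PX, PY)
    hit = RawHit(score, qi0, int(i), tj0 + t_offset, int(j) + t_offset,
                 [(op, qi, ts + t_offset, ln) for op, qi, ts, ln in cols])
    hits = [hit]
    # recurse on the flanking target segments for further non-overlapping hits
    left = t[:tj0]
    right = t[int(j):]
    if left.shape[0] >= 6:
        hits.extend(_dp_hits(q, left, params, t_offset))
    if right.shape[0] >= 6:
        hits.extend(_dp_hits(q, right, params, t_offset + int(j)))
    return hits


@dataclass
class ProteinHit:
    """A local alignment of a protein query against genomic DNA."""

    query_id: str
    contig_id: str
    strand: str
    t_start: int          # forward-strand genomic coords, 0-based half-open
    t_end: int
    q_start: int
    q_end: int
    score: int
    identity: float
    coverage: float
    aligned_length: int   # aa positions aligned to target
    query_length: int
    n_frameshifts: int
    net_frameshift: int   # (sum of insert nt - frame slippage) mod 3
    # columns in strand space of the searched sequence (see target_sequence)
    columns: list[tuple[int, int, int, int]] = field(default_factory=list)
    ts_length: int = 0    # length of the strand-space target the columns index

    @property
    def interval(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)

    def gap_structure(self) -> list[tuple[int, int]]:
        """(query position, target insertion length nt) for each insertion."""
        out = []
        last_q = self.q_start
        for op, qi, ts, ln in self.columns:
            if op == OP_MATCH:
                last_q = qi + 1
            elif op == OP_INS:
                out.append((last_q, ln))
        return out

    def aligned_codons(self, target_strand_seq: str) -> list[tuple[int, str]]:
        """(query index, consumed target nt) for in-frame (3-nt) match columns."""
        return [
            (qi, target_strand_seq[ts : ts + ln])
            for op, qi, ts, ln in self.columns
            if op == OP_MATCH and ln == 3
        ]


def _annotate(raw: RawHit, query: np.ndarray, t_enc: np.ndarray,
              query_id: str, contig_id: str, strand: str, ts_len: int,
              params: AlignmentParams) -> ProteinHit:
    sub, codon_aa = _tables()
    ident = 0
    aligned = 0
    n_fs = 0
    net = 0
    for op, qi, ts, ln in raw.columns:
        if op == OP_MATCH:
            aligned += 1
            if ln == 3:
                code = int(t_enc[ts]) * 25 + int(t_enc[ts + 1]) * 5 + int(t_enc[ts + 2])
                if codon_aa[code] == query[qi]:
                    ident += 1
            else:
                n_fs += 1
                net += ln - 3
        elif op == OP_INS:
            net += ln
    m = query.shape[0]
    if strand == "+":
        f_start, f_end = raw.t_start, raw.t_end
    else:
        f_start, f_end = ts_len - raw.t_end, ts_len - raw.t_start
    return ProteinHit(
        query_id=query_id, contig_id=contig_id, strand=strand,
        t_start=f_start, t_end=f_end, q_start=raw.q_start, q_end=raw.q_end,
        score=raw.score,
        identity=ident / aligned if aligned else 0.0,
        coverage=aligned / m if m else 0.0,
        aligned_length=aligned, query_length=m,
        n_frameshifts=n_fs, net_frameshift=net % 3,
        columns=raw.columns, ts_length=ts_len,
    )


def align_protein_to_target(
    protein: str, target: str, params: AlignmentParams | None = None,
    query_id: str = "query", contig_id: str = "target",
    strands: str = "+-",
) -> list[ProteinHit]:
    """Frameshift-tolerant local alignment of a protein against one sequence.

    Exhaustive over the full target (both strands by default); hits sorted by
    score descending.
    """
    params = params or AlignmentParams()
    q = encode_protein(protein)
    hits: list[ProteinHit] = []
    for strand in strands:
        ts = target if strand == "+" else str(Seq(target).reverse_complement())
        t_enc = encode_nt(ts)
        for raw in _dp_hits(q, t_enc, params):
            hits.append(_annotate(raw, q, t_enc, query_id, contig_id, strand,
                                  len(ts), params))
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.t_start))
    return hits


class GenomeIndex:
    """Exact peptide 5-mer index over the six-frame translation of a genome."""

    def __init__(self, genome: Mapping[str, GenomeSequence], k: int = 5):
        self.k = k
        self.genome = genome
        self.strand_seq: dict[tuple[str, str], str] = {}
        self.kmers: dict[str, list[tuple[str, str, int]]] = {}
        for cid, contig in genome.items():
            for strand in "+-":
                ts = (contig.sequence if strand == "+"
                      else str(Seq(contig.sequence).reverse_complement()))
                self.strand_seq[(cid, strand)] = ts
                for frame in range(3):
                    prot = str(Seq(ts[frame:len(ts) - (len(ts) - frame) % 3]).translate())
                    for p in range(len(prot) - k + 1):
                        kmer = prot[p : p + k]
                        if "*" in kmer or "X" in kmer:
                            continue
                        self.kmers.setdefault(kmer, []).append(
                            (cid, strand, frame + 3 * p)
                        )

    def seed_windows(self, protein: str, pad: int) -> dict[tuple[str, str], list[tuple[int, int]]]:
        """Merged candidate windows (strand-space nt coords) per contig/strand."""
        k = self.k
        raw: dict[tuple[str, str], list[int]] = {}
        for p in range(len(protein) - k + 1):
            for cid, strand, ts_pos in self.kmers.get(protein[p : p + k], ()):
                raw.setdefault((cid, strand), []).append(ts_pos)
        out: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for key, positions in raw.items():
            ts_len = len(self.strand_seq[key])
            positions.sort()
            windows: list[list[int]] = []
            for pos in positions:
                if windows and pos - windows[-1][1] <= pad:
                    windows[-1][1] = pos
                else:
                    windows.append([pos, pos])
            out[key] = [
                (max(0, a - pad), min(ts_len, b + 3 * k + pad)) for a, b in windows
            ]
        return out


def align_protein_to_genome(
    protein: str,
    genome: Mapping[str, GenomeSequence],
    params: AlignmentParams | None = None,
    query_id: str = "query",
    index: GenomeIndex | None = None,
) -> list[ProteinHit]:
    """Search a protein against all six frames of every contig.

    Contigs up to ``params.full_dp_threshold`` nt are solved exhaustively;
    larger targets are restricted to exact-peptide seed windows first.
    """
    params = params or AlignmentParams()
    if len(protein) < 20:
        raise ValueError("protein query shorter than 20 aa")
    q = encode_protein(protein)
    hits: list[ProteinHit] = []
    small = {cid: c for cid, c in genome.items()
             if c.length <= params.full_dp_threshold}
    large = {cid: c for cid, c in genome.items() if cid not in small}
    for cid, contig in small.items():
        hits.extend(
            align_protein_to_target(protein, contig.sequence, params,
                                    query_id=query_id, contig_id=cid)
        )
    if large:
        if index is None:
            index = GenomeIndex(large, k=params.seed_k)
        pad = 3 * len(protein) + params.seed_window_pad
        for (cid, strand), windows in index.seed_windows(protein, pad).items():
            if cid not in large:
                continue
            ts = index.strand_seq[(cid, strand)]
            for w0, w1 in windows:
                t_enc = encode_nt(ts[w0:w1])
                for raw in _dp_hits(q, t_enc, params, t_offset=0):
                    # shift columns/coords into full strand space
                    raw = RawHit(
                        raw.score, raw.q_start, raw.q_end,
                        raw.t_start + w0, raw.t_end + w0,
                        [(op, qi, tss + w0, ln) for op, qi, tss, ln in raw.columns],
                    )
                    full_enc = encode_nt(ts)
                    hits.append(_annotate(raw, q, full_enc, query_id, cid,
                                          strand, len(ts), params))
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.t_start))
    return hits


# ---------------------------------------------------------------------------
# global protein-protein alignment
# ---------------------------------------------------------------------------

@dataclass
class GlobalProteinAlignment:
    score: float
    identity: float
    coverage_a: float
    coverage_b: float
    pairs: list[tuple[int | None, int | None]]  # aligned index columns

    @property
    def aligned_length(self) -> int:
        return sum(1 for a, b in self.pairs if a is not None and b is not None)


def align_proteins_global(
    a: str, b: str, params: AlignmentParams | None = None
) -> GlobalProteinAlignment:
    """Optimal global alignment under BLOSUM62 with affine gaps."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    params = params or AlignmentParams()
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-params.open_cost,
        extend_gap_score=-params.gap_extend,
    )
    aln = aligner.align(a, b)[0]
    pairs: list[tuple[int | None, int | None]] = []
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        # blocks of aligned coordinates
        for off in range(a1 - a0):
            i, j = a0 + off, b0 + off
            pairs.append((i, j))
            if a[i] == b[j]:
                ident += 1
    # interleave gap columns for completeness
    full: list[tuple[int | None, int | None]] = []
    pi, pj = 0, 0
    for i, j in pairs:
        while pi < i:
            full.append((pi, None))
            pi += 1
        while pj < j:
            full.append((None, pj))
            pj += 1
        full.append((i, j))
        pi, pj = i + 1, j + 1
    while pi < len(a):
        full.append((pi, None))
        pi += 1
    while pj < len(b):
        full.append((None, pj))
        pj += 1
    aligned = len(pairs)
    return GlobalProteinAlignment(
        score=float(aln.score),
        identity=ident / aligned if aligned else 0.0,
        coverage_a=aligned / len(a),
        coverage_b=aligned / len(b),
        pairs=full,
    )


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Two gap-padded coding sequences with gaps in whole-codon units."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("codon alignment sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("codon alignment length not divisible by 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Gap-free, N-free codon pairs."""
        out = []
        for k in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[k : k + 3], self.seq_b[k : k + 3]
            if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
                continue
            out.append((ca, cb))
        return out


def build_codon_alignment(
    parent_cds: str, retro_cds: str,
    protein_alignment: GlobalProteinAlignment | None = None,
) -> CodonAlignment:
    """Back-propagate a protein alignment onto the two coding sequences.

    Terminal stop codons are trimmed.  Each protein-alignment column expands to
    one codon column; gaps therefore appear in whole-codon units.
    """
    def _trim(cds: str) -> str:
        if len(cds) % 3 == 0 and len(cds) >= 3:
            if str(Seq(cds[-3:]).translate()) == "*":
                return cds[:-3]
        return cds

    a_cds, b_cds = _trim(parent_cds.upper()), _trim(retro_cds.upper())
    if len(a_cds) % 3 or len(b_cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    pa = str(Seq(a_cds).translate()).replace("*", "X")
    pb = str(Seq(b_cds).translate()).replace("*", "X")
    if protein_alignment is None:
        protein_alignment = align_proteins_global(pa, pb)
    else:
        if len(pa) != sum(1 for i, _ in protein_alignment.pairs if i is not None):
            raise ValueError("parent CDS does not match protein alignment length")
        if len(pb) != sum(1 for _, j in protein_alignment.pairs if j is not None):
            raise ValueError("retro CDS does not match protein alignment length")
    sa, sb = [], []
    for i, j in protein_alignment.pairs:
        sa.append(a_cds[3 * i : 3 * i + 3] if i is not None else "---")
        sb.append(b_cds[3 * j : 3 * j + 3] if j is not None else "---")
    return CodonAlignment("".join(sa), "".join(sb))


# ---------------------------------------------------------------------------
# nucleotide identity
# ---------------------------------------------------------------------------

def nt_identity(a: str, b: str) -> tuple[float, float, int]:
    """(identity, coverage, aligned_length) from a global nt alignment.

    identity = matches / aligned columns (both sequences non-gap);
    coverage = aligned columns / longer sequence length.
    """
    import edlib

    if not a or not b:
        raise ValueError("empty sequence")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = mismatches = 0
    for count, op in _parse_cigar(res["cigar"]):
        if op == "=":
            matches += count
        elif op == "X":
            mismatches += count
    aligned = matches + mismatches
    identity = matches / aligned if aligned else 0.0
    coverage = aligned / max(len(a), len(b))
    return identity, coverage, aligned


def _parse_cigar(cigar: str) -> Iterable[tuple[int, str]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
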
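"""Expression computations on FPKM matrices.

Covers per-tissue/stage expressed counts, tissue specificity and testis bias,
parent-retrocopy Pearson correlation with Benjamini-Hochberg FDR and the
strong/weak/none category bands, the Y = ln((1+R)/(1-R)) transform and its
regression on Ks, young/old/parent group comparisons, and the 2^-ddCt
fold-change arithmetic used for qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

CATEGORIES = ("strong_positive", "weak_positive", "weak_negative",
              "strong_negative", "none")


@dataclass
class ExpressionSummary:
    counts: dict[tuple[str, str], int]      # (tissue, stage) -> expressed count
    threshold: float
    missing_columns: list[tuple[str, str]]


@dataclass
class CorrelationResult:
    retro_id: str
    parent_id: str
    r: float
    p: float
    q: float
    category: str
    n_samples: int
    flagged: bool = False       # zero-variance input, R undefined


def _check_ids(matrix: ExpressionMatrix, ids: Sequence[str]) -> None:
    missing = [i for i in ids if i not in matrix.values.index]
    if missing:
        raise KeyError(f"ids absent from expression matrix: {missing}")


def expressed_counts(
    matrix: ExpressionMatrix, ids: Sequence[str], threshold: float = 0.0,
    expected_columns: Sequence[tuple[str, str]] | None = None,
) -> ExpressionSummary:
    """Per-(tissue, stage) count of ids with FPKM above the threshold.

    ``expected_columns`` lets callers ask for a fixed tissue/stage grid;
    columns absent from the matrix are reported as 0 and flagged in
    ``missing_columns`` (no transcriptome sample for that combination).
    """
    _check_ids(matrix, ids)
    sub = matrix.values.loc[list(ids)]
    counts = {}
    for col in sub.columns:
        counts[col] = int((sub[col] > threshold).sum())
    missing = []
    if expected_columns is not None:
        for col in expected_columns:
            if col not in counts:
                counts[col] = 0
                missing.append(col)
    return ExpressionSummary(counts=counts, threshold=threshold,
                             missing_columns=missing)


def tissue_specific_counts(
    matrix: ExpressionMatrix, ids: Sequence[str], stage: str,
    threshold: float = 0.0,
) -> tuple[dict[str, int], float | None]:
    """Tissue-specific counts at one stage, plus the testis excess ratio.

    A record is specific to tissue t when its FPKM exceeds the threshold in t
    and nowhere else at that stage.  The excess ratio is the testis-specific
    count over the mean specific count of the other tissues (None when that
    mean is zero).
    """
    _check_ids(matrix, ids)
    cols = [c for c in matrix.values.columns if c[1] == stage]
    tissues = [c[0] for c in cols]
    if len(tissues) < 2:
        raise ValueError(f"stage {stage!r} has fewer than 2 tissues")
    sub = matrix.values.loc[list(ids), cols]
    expressed = sub.to_numpy() > threshold
    specific = {t: 0 for t in tissues}
    for row in expressed:
        if row.sum() == 1:
            specific[tissues[int(np.argmax(row))]] += 1
    excess = None
    if "testis" in specific:
        others = [v for t, v in specific.items() if t != "testis"]
        mean_others = float(np.mean(others)) if others else 0.0
        excess = specific["testis"] / mean_others if mean_others > 0 else None
    return specific, excess


def categorize(r: float, significant: bool) -> str:
    """Correlation category from the |R| bands, gated on significance."""
    if not significant or not np.isfinite(r) or abs(r) < 0.3:
        return "none"
    if r > 0.8:
        return "strong_positive"
    if r > 0.3:
        return "weak_positive"
    if r < -0.8:
        return "strong_negative"
    if r < -0.3:
        return "weak_negative"
    return "none"


def pair_correlations(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    min_samples: int = 3,
    alpha: float = 0.05,
    gate_on: str = "q",
) -> list[CorrelationResult]:
    """Pearson R with BH-FDR across parent-retrocopy pairs.

    Pairs whose retrocopy row is entirely zero are removed before testing
    (they are unexpressed, not uncorrelated).  Categories follow the |R|
    bands and are assigned only to pairs significant at ``alpha`` after BH
    adjustment (or on raw p with ``gate_on='p'``).
    """
    kept: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for rid, pid in pairs:
        _check_ids(matrix, [rid, pid])
        x = matrix.row(rid)
        y = matrix.row(pid)
        if not np.any(x > 0):
            continue
        if len(x) < min_samples:
            raise ValueError(f"pair ({rid}, {pid}) has fewer than "
                             f"{min_samples} matched samples")
        kept.append((rid, pid, x, y))
    results: list[CorrelationResult] = []
    ps: list[float] = []
    for rid, pid, x, y in kept:
        if np.std(x) == 0 or np.std(y) == 0:
            results.append(CorrelationResult(rid, pid, float("nan"), 1.0, 1.0,
                                             "none", len(x), flagged=True))
            ps.append(1.0)
            continue
        r, p = stats.pearsonr(x, y)
        results.append(CorrelationResult(rid, pid, float(r), float(p), 1.0,
                                         "none", len(x)))
        ps.append(float(p))
    if results:
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
        for res, q in zip(results, qs):
            res.q = float(q)
            gate = res.q if gate_on == "q" else res.p
            res.category = ("none" if res.flagged
                            else categorize(res.r, gate < alpha))
    return results


def fisher_y(r: float) -> float:
    """Y = ln((1 + R) / (1 - R)); odd in R, defined for |R| < 1."""
    if abs(r) >= 1:
        raise ValueError("|R| must be < 1")
    return float(np.log((1 + r) / (1 - r)))


def regress_y_on_ks(
    ks_values: Sequence[float], y_values: Sequence[float]
) -> dict[str, float]:
    """OLS of Y on Ks with the slope t-test; returns slope/intercept/R2/p."""
    ks = np.asarray(ks_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    mask = np.isfinite(ks) & np.isfinite(y)
    ks, y = ks[mask], y[mask]
    if ks.size < 3:
        raise ValueError("need at least 3 finite (ks, Y) pairs")
    if np.std(ks) == 0:
        raise ValueError("degenerate design: Ks has zero variance")
    if np.std(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                "p_value": 1.0, "n": int(ks.size)}
    res = stats.linregress(ks, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "p_value": float(res.pvalue),
        "n": int(ks.size),
    }


def compare_group_expression(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
    test: str = "mannwhitney",
) -> list[dict]:
    """Pairwise two-sided tests between expression groups with BH adjustment.

    Default test is Mann-Whitney U; ``test='ttest'`` switches to Welch's t.
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    comps = []
    ps = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            if test == "ttest":
                stat, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            comps.append({"group_a": names[i], "group_b": names[j],
                          "statistic": float(stat), "p": float(p)})
            ps.append(float(p))
    if comps:
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
        for c, q in zip(comps, qs):
            c["q"] = float(q)
            c["significant"] = bool(q < alpha)
    return comps


def ddct_fold_change(
    ct_target_case: float, ct_ref_case: float,
    ct_target_ctrl: float, ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
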
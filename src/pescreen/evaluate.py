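"""Screening-performance statistics: ROC/AUC, cutoffs, fixed-FPR rates, CIs.

Conventions
-----------
* A record is screen positive at threshold ``t`` when its risk score is
  ``>= t``.
* AUC is the concordant-pair probability (Mann-Whitney statistic with ties
  counted half), identical to the trapezoidal area under the empirical ROC.
* The AUC confidence interval and the paired comparison of two correlated
  AUCs use DeLong's structural-components method.
* Fixed-FPR thresholds take the strictest threshold whose *empirical* FPR
  does not exceed the target — no interpolation, so results are exactly
  reproducible on finite cohorts.
* Binomial confidence intervals for DR/FPR/PPV are exact (Clopper-Pearson,
  via beta quantiles), the method that reproduces published screening tables
  such as 7/8 -> 47.35-99.68%.

Percentages are returned on the 0-100 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ROCResult",
    "CutoffResult",
    "FixedFPRResult",
    "roc_auc",
    "compare_auc",
    "best_cutoff",
    "dr_at_fpr",
    "clopper_pearson",
    "mann_whitney",
    "summarize_group_moms",
    "fixed_fpr_table",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both affected and unaffected records are required")
    return labels


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC: thresholds ascending, sensitivity non-increasing."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]


class CutoffResult(NamedTuple):
    threshold: float
    dr_pct: float
    fpr_pct: float


class FixedFPRResult(NamedTuple):
    threshold: float
    dr_pct: float
    ppv_pct: float
    fpr_pct: float


# ---------------------------------------------------------------------------
# DeLong structural components
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) of a 1-D array."""
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong AUCs and covariance for k score vectors over shared labels.

    ``scores``: (k, n) array; returns ``(aucs (k,), cov (k, k))``.
    """
    labels = _check_binary(labels)
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midranks(pos[r])
        ty = _midranks(neg[r])
        tz = _midranks(np.concatenate([pos[r], neg[r]]))
        aucs[r] = tz[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    sx = np.atleast_2d(np.cov(v01)) if m > 1 else np.zeros((k, k))
    sy = np.atleast_2d(np.cov(v10)) if n > 1 else np.zeros((k, k))
    cov = sx / m + sy / n
    return aucs, cov


def roc_auc(scores, labels, conf: float = 0.95) -> ROCResult:
    """Empirical ROC with rank-statistic AUC and a DeLong confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    # roc_curve orders thresholds descending; store ascending-threshold view.
    order = np.argsort(thr)
    thresholds = thr[order]
    sensitivity = tpr[order]
    specificity = 1.0 - fpr[order]
    _, cov = _delong(scores[None, :], labels)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        auc_ci=ci,
    )


def compare_auc(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong comparison of two correlated AUCs: ``(delta, p)``.

    ``delta = AUC(a) - AUC(b)``; p is the two-sided normal p-value.  When the
    score vectors are identical the difference is exactly 0 with p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"score vectors differ in length: {a.shape} vs {b.shape}")
    aucs, cov = _delong(np.vstack([a, b]), labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        return delta, 1.0 if delta == 0.0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return delta, p


def best_cutoff(roc: ROCResult) -> CutoffResult:
    """Threshold maximizing mean of sensitivity and specificity (Youden-style).

    Ties are broken toward the lower false-positive rate.
    """
    avg = (roc.sensitivity + roc.specificity) / 2.0
    best = avg.max()
    candidates = np.flatnonzero(np.isclose(avg, best, rtol=0.0, atol=1e-12))
    fpr = 1.0 - roc.specificity
    pick = candidates[np.argmin(fpr[candidates])]
    return CutoffResult(
        threshold=float(roc.thresholds[pick]),
        dr_pct=float(roc.sensitivity[pick] * 100.0),
        fpr_pct=float(fpr[pick] * 100.0),
    )


def dr_at_fpr(scores, labels, target_fpr_pct: float) -> FixedFPRResult:
    """Detection rate and PPV at the strictest threshold with FPR <= target.

    The threshold is the smallest candidate score value whose empirical FPR
    among unaffected records does not exceed ``target_fpr_pct``; smaller
    thresholds admit more positives, so this maximizes DR subject to the FPR
    constraint.
    """
    if not 0.0 < target_fpr_pct <= 100.0:
        raise ValueError(f"target FPR must be in (0, 100], got {target_fpr_pct}")
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    neg = np.sort(scores[~labels])
    pos = np.sort(scores[labels])
    candidates = np.unique(scores)
    # FPR(t) = fraction of negatives >= t, vectorized via searchsorted.
    n_neg_ge = len(neg) - np.searchsorted(neg, candidates, side="left")
    fpr = n_neg_ge / len(neg)
    feasible = fpr <= target_fpr_pct / 100.0
    if feasible.any():
        idx = int(np.flatnonzero(feasible)[0])  # candidates ascending: smallest t
        threshold = float(candidates[idx])
        fp = int(n_neg_ge[idx])
    else:  # no attainable threshold (massive ties): nothing screens positive
        threshold = float(np.inf)
        fp = 0
    tp = int(len(pos) - np.searchsorted(pos, threshold, side="left"))
    dr = 100.0 * tp / len(pos)
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return FixedFPRResult(
        threshold=threshold,
        dr_pct=dr,
        ppv_pct=ppv,
        fpr_pct=100.0 * fp / len(neg),
    )


def clopper_pearson(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI via beta quantiles, in percent."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - conf
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2.0, successes, n - successes + 1)
    hi = 1.0 if successes == n else stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
    return float(lo * 100.0), float(hi * 100.0)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: ``(U, p)``.

    Exact enumeration for small tie-free samples (n_a * n_b <= 400), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Report builders
# ---------------------------------------------------------------------------

def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def summarize_group_moms(
    frame: pd.DataFrame,
    mom_columns: Sequence[str] = ("mom_plgf", "mom_pappa", "mom_map"),
) -> pd.DataFrame:
    """Median (IQR) of each MoM per outcome group, with Mann-Whitney p-values.

    ``frame`` needs the MoM columns plus ``pe_status`` and ``sga``.  Each
    group is compared against its unaffected complement (unaffected-by-PE for
    the PE rows, unaffected-by-SGA for the SGA rows).  Empty groups emit a
    row with ``n = 0`` and no test.
    """
    pe = frame["pe_status"].astype(str)
    sga = frame["sga"].fillna(0).astype(float) > 0
    groups = {
        "unaffected_by_pe": (pe == "none", None),
        "pe": (pe != "none", "unaffected_by_pe"),
        "early_pe": (pe == "early", "unaffected_by_pe"),
        "late_pe": (pe == "late", "unaffected_by_pe"),
        "pe_with_sga": ((pe != "none") & sga, "unaffected_by_pe"),
        "unaffected_by_sga": (~sga, None),
        "sga": (sga, "unaffected_by_sga"),
        "sga_without_pe": (sga & (pe == "none"), "unaffected_by_sga"),
    }
    rows = []
    for name, (mask, ref) in groups.items():
        row: dict[str, object] = {"group": name, "n": int(mask.sum())}
        for col in mom_columns:
            if mask.sum() == 0:
                row[f"{col}_median"] = np.nan
                row[f"{col}_q1"] = np.nan
                row[f"{col}_q3"] = np.nan
                row[f"{col}_p"] = np.nan
                continue
            med, q1, q3 = _median_iqr(frame.loc[mask, col].to_numpy(float))
            row[f"{col}_median"] = med
            row[f"{col}_q1"] = q1
            row[f"{col}_q3"] = q3
            if ref is None or mask.sum() == 0:
                row[f"{col}_p"] = np.nan
            else:
                ref_mask = groups[ref][0]
                _, p = mann_whitney(
                    frame.loc[mask, col].to_numpy(float),
                    frame.loc[ref_mask, col].to_numpy(float),
                )
                row[f"{col}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def fixed_fpr_table(
    scores: np.ndarray,
    subgroups: dict[str, np.ndarray],
    unaffected: np.ndarray,
    fpr_targets: Sequence[float] = (5.0, 10.0, 15.0),
    conf: float = 0.95,
) -> pd.DataFrame:
    """Detection rates/PPVs of outcome subgroups at shared fixed-FPR cutoffs.

    The threshold per FPR target is set once on ``unaffected`` (records
    unaffected by both conditions); each subgroup's DR is its fraction above
    that threshold, and PPV counts that subgroup's true positives against the
    unaffected false positives.  All rates carry exact binomial CIs, and the
    threshold is also reported as a "1:N" risk cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    unaffected = np.asarray(unaffected, dtype=bool)
    rows = []
    for target in fpr_targets:
        neg = np.sort(scores[unaffected])
        candidates = np.unique(scores)
        n_ge = len(neg) - np.searchsorted(neg, candidates, side="left")
        feasible = (n_ge / len(neg)) <= target / 100.0
        threshold = float(candidates[np.flatnonzero(feasible)[0]]) if feasible.any() else np.inf
        fp = int((scores[unaffected] >= threshold).sum())
        # "1:N" only meaningful for probability-scale thresholds of sane size
        cutoff_n = int(round(1.0 / threshold)) if 1e-6 < threshold < 1 else None
        for name, mask in subgroups.items():
            mask = np.asarray(mask, dtype=bool)
            n_sub = int(mask.sum())
            tp = int((scores[mask] >= threshold).sum())
            dr = 100.0 * tp / n_sub if n_sub else np.nan
            dr_ci = clopper_pearson(tp, n_sub, conf) if n_sub else (np.nan, np.nan)
            ppv = 100.0 * tp / (tp + fp) if (tp + fp) else np.nan
            ppv_ci = clopper_pearson(tp, tp + fp, conf) if (tp + fp) else (np.nan, np.nan)
            rows.append(
                {
                    "fpr_target_pct": target,
                    "risk_cutoff": f"1:{cutoff_n}" if cutoff_n else "NA",
                    "subgroup": name,
                    "n": n_sub,
                    "dr_pct": dr,
                    "dr_ci_lo": dr_ci[0],
                    "dr_ci_hi": dr_ci[1],
                    "ppv_pct": ppv,
                    "ppv_ci_lo": ppv_ci[0],
                    "ppv_ci_hi": ppv_ci[1],
                    "fpr_pct": 100.0 * fp / int(unaffected.sum()),
                }
            )
    return pd.DataFrame(rows)
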
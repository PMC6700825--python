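"""Gestational-age median models and multiple-of-median (MoM) computation.

A marker level is normalized to a MoM by dividing it by the expected median
for the same gestational age; serum markers (PLGF, PAPP-A) are additionally
adjusted for maternal weight, ethnicity and smoking.  MAP MoM is GA-adjusted
only.  Expected medians follow the screening-literature convention of a
regression of log10(level) on gestational age in days:

    median(ga) = 10 ** (intercept + slope * ga_days)

The weight adjustment is log-linear in centered weight; ethnicity and smoking
enter as multiplicative MoM factors (reference categories have factor 1).
Adjusted log10 MoM values are truncated to configurable limits to keep
downstream likelihood ratios bounded.

The fit-shaped surface is :class:`MoMTransformer`, an sklearn-style
transformer; the module-level functions wrap the same arithmetic for single
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import GA_WINDOW_DAYS

__all__ = [
    "MarkerMedianModel",
    "MedianModel",
    "MoMTransformer",
    "fit_median_model",
    "expected_median",
    "compute_mom",
    "adjust_mom",
    "truncate_log_mom",
    "MARKERS",
    "ADJUSTED_MARKERS",
    "DEFAULT_TRUNCATION",
]

MARKERS = ("map", "plgf", "pappa")
#: Markers whose MoM receives weight/ethnicity/smoking adjustment.
ADJUSTED_MARKERS = ("plgf", "pappa")
#: Default truncation limits for adjusted log10 MoM.
DEFAULT_TRUNCATION = (-1.0, 1.0)


@dataclass(frozen=True)
class MarkerMedianModel:
    """Expected-median model for one marker."""

    intercept: float  # log10(level) at ga = 0 days
    slope: float  # d log10(level) / d ga_day
    weight_slope: float = 0.0  # d log10(MoM) / d kg, centered at reference_weight
    ethnicity_factors: Mapping[str, float] = field(default_factory=lambda: {"chinese": 1.0})
    smoking_factor: float = 1.0


@dataclass(frozen=True)
class MedianModel:
    markers: Mapping[str, MarkerMedianModel]
    reference_weight: float = 53.0  # kg
    ga_window: tuple[int, int] = GA_WINDOW_DAYS
    truncation: tuple[float, float] = DEFAULT_TRUNCATION


def expected_median(model: MedianModel, marker: str, ga_days: float) -> float:
    """Expected marker median at a gestational age within the screening window."""
    lo, hi = model.ga_window
    ga = np.asarray(ga_days, dtype=float)
    if np.any(ga < lo) or np.any(ga > hi):
        raise ValueError(f"GA outside screening window [{lo}, {hi}] days")
    spec = model.markers[marker]
    out = 10.0 ** (spec.intercept + spec.slope * ga)
    return float(out) if np.isscalar(ga_days) else out


def compute_mom(level, expected):
    """Multiple of median: observed level over the expected median."""
    level = np.asarray(level, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(level <= 0) or np.any(expected <= 0):
        raise ValueError("levels and expected medians must be positive")
    out = level / expected
    return float(out) if out.ndim == 0 else out


def _adjustment_factor(model: MedianModel, marker: str, weight, ethnicity, smoking):
    """Multiplicative divisor applied to a raw MoM for covariate adjustment."""
    spec = model.markers[marker]
    weight = np.asarray(weight, dtype=float)
    eth = np.asarray(ethnicity, dtype=object)
    known = set(spec.ethnicity_factors)
    categories = set(np.unique(eth).tolist())
    unknown = categories - known
    if unknown:
        raise ValueError(f"unknown ethnicity category: {sorted(unknown)}")
    eth_factor = np.vectorize(spec.ethnicity_factors.__getitem__, otypes=[float])(eth)
    smoke = np.asarray(smoking, dtype=float)
    smoke_factor = np.where(smoke > 0, spec.smoking_factor, 1.0)
    return (
        10.0 ** (spec.weight_slope * (weight - model.reference_weight))
        * eth_factor
        * smoke_factor
    )


def adjust_mom(raw_mom, marker: str, model: MedianModel, weight, ethnicity, smoking):
    """Covariate-adjust a raw MoM (PLGF/PAPP-A only; MAP passes through)."""
    raw_mom = np.asarray(raw_mom, dtype=float)
    if np.any(raw_mom <= 0):
        raise ValueError("MoM must be positive")
    if marker not in ADJUSTED_MARKERS:
        return float(raw_mom) if raw_mom.ndim == 0 else raw_mom
    out = raw_mom / _adjustment_factor(model, marker, weight, ethnicity, smoking)
    return float(out) if out.ndim == 0 else out


def truncate_log_mom(value, limits: tuple[float, float] = DEFAULT_TRUNCATION):
    """Clamp a log10 MoM to ``limits``; returns ``(clamped, was_truncated)``."""
    lo, hi = limits
    if not lo < hi:
        raise ValueError(f"invalid truncation limits {limits}")
    value = np.asarray(value, dtype=float)
    clamped = np.clip(value, lo, hi)
    flag = clamped != value
    if value.ndim == 0:
        return float(clamped), bool(flag)
    return clamped, flag


class MoMTransformer(TransformerMixin, BaseEstimator):
    """Fit gestational-age median models and transform levels to adjusted MoM.

    Parameters
    ----------
    unaffected_only : bool
        When a label vector ``y`` is passed to :meth:`fit`, restrict the fit
        to rows with ``y == "none"`` (median models describe the unaffected
        population).
    reference_weight : float or None
        Centering weight (kg) for the weight adjustment; ``None`` uses the
        training-cohort median.
    truncation : (float, float)
        Truncation limits for adjusted log10 MoM.
    median_model : MedianModel or None
        A pre-specified model; when given, :meth:`fit` only validates and
        stores it (no refitting) so externally calibrated medians can be used.

    Input frames need columns ``map``, ``plgf``, ``pappa`` (levels in mmHg,
    pg/mL, mU/L), ``ga_days``, ``weight``, ``ethnicity``, ``smoking``.
    """

    MIN_TRAINING = 50

    def __init__(
        self,
        unaffected_only: bool = True,
        reference_weight: float | None = None,
        truncation: tuple[float, float] = DEFAULT_TRUNCATION,
        median_model: MedianModel | None = None,
    ):
        self.unaffected_only = unaffected_only
        self.reference_weight = reference_weight
        self.truncation = truncation
        self.median_model = median_model

    def fit(self, X: pd.DataFrame, y=None) -> "MoMTransformer":
        if self.median_model is not None:
            self.median_model_ = replace(self.median_model, truncation=tuple(self.truncation))
            return self
        frame = X
        if y is not None and self.unaffected_only:
            frame = X.loc[np.asarray(y) == "none"]
        if len(frame) < self.MIN_TRAINING:
            raise ValueError(
                f"need >= {self.MIN_TRAINING} training records, got {len(frame)}"
            )
        ga = frame["ga_days"].to_numpy(dtype=float)
        if np.unique(ga).size < 2:
            raise ValueError("degenerate design: a single gestational-age value")
        ref_weight = (
            float(np.median(frame["weight"]))
            if self.reference_weight is None
            else float(self.reference_weight)
        )
        markers: dict[str, MarkerMedianModel] = {}
        for marker in MARKERS:
            level = frame[marker].to_numpy(dtype=float)
            if np.any(level <= 0):
                raise ValueError(f"nonpositive {marker} level in training data")
            slope, intercept = np.polyfit(ga, np.log10(level), 1)
            spec = MarkerMedianModel(intercept=float(intercept), slope=float(slope))
            if marker in ADJUSTED_MARKERS:
                log_mom = np.log10(level) - (intercept + slope * ga)
                dw = frame["weight"].to_numpy(dtype=float) - ref_weight
                w_slope = float(np.polyfit(dw, log_mom, 1)[0]) if np.ptp(dw) > 0 else 0.0
                resid = log_mom - w_slope * dw
                eth = frame["ethnicity"].astype(str).to_numpy()
                smoke = frame["smoking"].to_numpy(dtype=float) > 0
                ref_mask = (eth == "chinese") & ~smoke
                if not ref_mask.any():  # fall back to whole sample as reference
                    ref_mask = np.ones_like(smoke, dtype=bool)
                ref_level = float(np.mean(resid[ref_mask & ~smoke])) if (ref_mask & ~smoke).any() else 0.0
                factors = {"chinese": 1.0}
                for cat in np.unique(eth):
                    if cat == "chinese":
                        continue
                    mask = (eth == cat) & ~smoke
                    factors[str(cat)] = (
                        float(10.0 ** (np.mean(resid[mask]) - ref_level)) if mask.any() else 1.0
                    )
                smoking_factor = (
                    float(10.0 ** (np.mean(resid[smoke]) - ref_level)) if smoke.any() else 1.0
                )
                spec = MarkerMedianModel(
                    intercept=float(intercept),
                    slope=float(slope),
                    weight_slope=w_slope,
                    ethnicity_factors=factors,
                    smoking_factor=smoking_factor,
                )
            markers[marker] = spec
        ga_window = (int(min(ga.min(), GA_WINDOW_DAYS[0])), int(max(ga.max(), GA_WINDOW_DAYS[1])))
        self.median_model_ = MedianModel(
            markers=markers,
            reference_weight=ref_weight,
            ga_window=ga_window,
            truncation=tuple(self.truncation),
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        model = self.median_model_
        ga = X["ga_days"].to_numpy(dtype=float)
        out = pd.DataFrame(index=X.index)
        for marker in MARKERS:
            expected = expected_median(model, marker, ga)
            raw = compute_mom(X[marker].to_numpy(dtype=float), expected)
            adj = adjust_mom(
                raw, marker, model, X["weight"], X["ethnicity"].astype(str), X["smoking"]
            )
            log_adj, flag = truncate_log_mom(np.log10(adj), model.truncation)
            out[f"mom_{marker}"] = 10.0 ** log_adj
            out[f"log10_mom_{marker}"] = log_adj
            out[f"truncated_{marker}"] = flag
        return out


def fit_median_model(
    training: pd.DataFrame,
    labels: Sequence[str] | None = None,
    unaffected_only: bool = True,
    reference_weight: float | None = None,
) -> MedianModel:
    """Functional wrapper over :class:`MoMTransformer` fitting."""
    transformer = MoMTransformer(
        unaffected_only=unaffected_only, reference_weight=reference_weight
    )
    transformer.fit(training, labels)
    return transformer.median_model_
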
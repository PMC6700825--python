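"""Prior and posterior preeclampsia risks by the Bayesian likelihood-ratio scheme.

The workflow mirrors first-trimester combined screening practice:

1.  A *prior* risk per horizon (early / late PE) from maternal characteristics:
    baseline odds multiplied by one positive likelihood ratio (LR) per factor
    (BMI band, ethnicity, parity, history of PE, chronic hypertension).
2.  Marker levels converted to adjusted MoM (see :mod:`pescreen.mom`).
3.  A marker LR: the ratio of multivariate Gaussian densities of the
    (MAP, PLGF, PAPP-A) log10 MoM triple under the affected vs unaffected
    hypothesis, evaluated in log space for numerical stability.
4.  The *posterior* risk: prior odds times marker LR, converted back to a
    probability.

Early and late PE are scored as two independent binary problems.  Risks are
reported clinically as "1 in N" with N = round(1/p); a pregnancy is screen
positive at cutoff 1:N when its risk probability is >= 1/N (boundary
inclusive, the aneuploidy-screening convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .cohort import MaternalRecord

__all__ = [
    "PriorModel",
    "GaussianModel",
    "RiskResult",
    "GaussianRiskModel",
    "prior_risk",
    "fit_gaussian_model",
    "marker_lr",
    "posterior_risk",
    "format_risk",
    "screen_positive",
    "DEFAULT_BMI_BANDS",
    "HORIZONS",
]

HORIZONS = ("early", "late")

#: BMI bands (kg/m^2) used by the banded prior: [lo, hi) half-open.
DEFAULT_BMI_BANDS = (("<25", 0.0, 25.0), ("25-30", 25.0, 30.0), (">=30", 30.0, np.inf))


@dataclass(frozen=True)
class PriorModel:
    """Baseline risks plus per-factor likelihood-ratio tables.

    ``lr_tables[horizon][factor][level]`` is a positive LR; reference levels
    carry LR 1.  Factors: ``bmi`` (band label), ``ethnicity`` (category),
    ``parity`` ("nulliparous"/"parous"), ``prior_pe`` and ``chronic_htn``
    (booleans keyed "true"/"false").
    """

    baseline: Mapping[str, float]  # horizon -> probability
    lr_tables: Mapping[str, Mapping[str, Mapping[str, float]]]
    bmi_bands: tuple = DEFAULT_BMI_BANDS

    def __post_init__(self) -> None:
        for horizon, p in self.baseline.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline risk for {horizon} must be in (0,1), got {p}")
        for horizon, table in self.lr_tables.items():
            for factor, levels in table.items():
                for level, lr in levels.items():
                    if lr <= 0:
                        raise ValueError(
                            f"LR for {horizon}/{factor}/{level} must be positive, got {lr}"
                        )

    def bmi_band(self, bmi: float) -> str:
        for label, lo, hi in self.bmi_bands:
            if lo <= bmi < hi:
                return label
        raise ValueError(f"BMI {bmi} not covered by any band")


def _factor_levels(record: MaternalRecord, model: PriorModel) -> dict[str, str]:
    return {
        "bmi": model.bmi_band(record.bmi),
        "ethnicity": record.ethnicity,
        "parity": record.parity,
        "prior_pe": "true" if record.prior_pe_history else "false",
        "chronic_htn": "true" if record.chronic_hypertension else "false",
    }


def prior_risk(record: MaternalRecord, model: PriorModel, horizon: str) -> float:
    """Prior probability of PE in ``horizon`` from the five maternal factors."""
    if horizon not in model.baseline:
        raise ValueError(f"unknown horizon {horizon!r}")
    p0 = model.baseline[horizon]
    odds = p0 / (1.0 - p0)
    table = model.lr_tables[horizon]
    for factor, level in _factor_levels(record, model).items():
        levels = table.get(factor, {})
        if level not in levels:
            raise ValueError(f"factor {factor!r} level {level!r} not in LR table")
        odds *= levels[level]
    return odds / (1.0 + odds)


def prior_risk_frame(frame: pd.DataFrame, model: PriorModel, horizon: str) -> np.ndarray:
    """Vectorized prior risk over a cohort DataFrame."""
    bmi = frame["weight_kg"].to_numpy(float) / (frame["height_cm"].to_numpy(float) / 100) ** 2
    p0 = model.baseline[horizon]
    odds = np.full(len(frame), p0 / (1.0 - p0))
    table = model.lr_tables[horizon]

    band_labels = np.empty(len(frame), dtype=object)
    for label, lo, hi in model.bmi_bands:
        band_labels[(bmi >= lo) & (bmi < hi)] = label
    levels = {
        "bmi": band_labels,
        "ethnicity": frame["ethnicity"].astype(str).to_numpy(),
        "parity": frame["parity"].astype(str).to_numpy(),
        "prior_pe": np.where(frame["prior_pe_history"].to_numpy(float) > 0, "true", "false"),
        "chronic_htn": np.where(
            frame["chronic_hypertension"].to_numpy(float) > 0, "true", "false"
        ),
    }
    for factor, level_arr in levels.items():
        mapping = table.get(factor, {})
        missing = set(np.unique(level_arr.astype(str))) - set(mapping)
        if missing:
            raise ValueError(f"factor {factor!r}: unmapped level(s) {sorted(missing)}")
        odds *= np.vectorize(mapping.__getitem__, otypes=[float])(level_arr)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class GaussianModel:
    """Per-hypothesis Gaussian parameters of the log10 MoM triple."""

    means: Mapping[str, np.ndarray]  # hypothesis -> (3,) mean vector
    covariances: Mapping[str, np.ndarray]  # hypothesis -> (3,3) SPD matrix
    markers: tuple[str, ...] = ("map", "plgf", "pappa")


def _log_mvn_density(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log multivariate-normal density via Cholesky (raises on non-PD cov)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    diff = x - mean
    solved = linalg.solve_triangular(chol, diff.T, lower=True)
    maha = np.sum(solved**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    k = mean.size
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + maha)


def marker_lr(x, affected: tuple, unaffected: tuple):
    """Likelihood ratio of Gaussian densities, affected over unaffected.

    ``affected`` / ``unaffected`` are ``(mean, covariance)`` pairs; ``x`` is a
    single log10 MoM vector or an (n, k) array.  Computed in log space.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    log_lr = _log_mvn_density(x, *affected) - _log_mvn_density(x, *unaffected)
    # keep the ratio positive and finite in double precision
    lr = np.exp(np.clip(log_lr, -700.0, 700.0))
    return float(lr[0]) if single else lr


def posterior_risk(prior, lr):
    """Posterior probability: prior odds times marker LR, back to probability."""
    prior = np.asarray(prior, dtype=float)
    lr = np.asarray(lr, dtype=float)
    if np.any(prior <= 0) or np.any(prior >= 1):
        raise ValueError("prior must lie strictly inside (0, 1)")
    if np.any(lr <= 0):
        raise ValueError("likelihood ratio must be positive")
    odds = prior / (1.0 - prior) * lr
    out = odds / (1.0 + odds)
    return float(out) if out.ndim == 0 else out


def format_risk(p: float) -> str:
    """Clinical "1 in N" formatting with N = round(1/p), at least 1."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must be in (0,1), got {p}")
    n = max(1, round(1.0 / p))
    return f"1 in {n}"


def screen_positive(p, cutoff_n: int):
    """Screen positive at cutoff 1:N iff risk probability >= 1/N (inclusive)."""
    if cutoff_n < 1:
        raise ValueError("cutoff N must be >= 1")
    p = np.asarray(p, dtype=float)
    out = p >= 1.0 / cutoff_n
    return bool(out) if out.ndim == 0 else out


class GaussianRiskModel(BaseEstimator):
    """Sklearn-style estimator of the per-hypothesis marker Gaussians.

    Parameters
    ----------
    covariance : {"full", "pooled", "diagonal"}
        "full" fits one covariance per hypothesis group; "pooled" shares the
        within-group covariance across hypotheses; "diagonal" zeroes
        off-diagonal terms of per-group covariances.
    unaffected_label : str
        Label of the unaffected hypothesis in ``y``.

    Fitted attributes: ``classes_``, ``means_`` (dict of (k,) vectors),
    ``covariances_`` (dict of (k,k) matrices), ``marker_names_``.
    """

    def __init__(self, covariance: str = "full", unaffected_label: str = "none"):
        self.covariance = covariance
        self.unaffected_label = unaffected_label

    def fit(self, X, y) -> "GaussianRiskModel":
        if self.covariance not in ("full", "pooled", "diagonal"):
            raise ValueError(f"unknown covariance mode {self.covariance!r}")
        if isinstance(X, pd.DataFrame):
            self.marker_names_ = tuple(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.marker_names_ = tuple(f"x{i}" for i in range(X.shape[1]))
        y = np.asarray(y)
        self.classes_ = tuple(sorted(np.unique(y).tolist()))
        means: dict[str, np.ndarray] = {}
        covs: dict[str, np.ndarray] = {}
        pooled_num = np.zeros((X.shape[1], X.shape[1]))
        pooled_dof = 0
        for cls in self.classes_:
            group = X[y == cls]
            if len(group) < 2:
                raise ValueError(f"hypothesis group {cls!r} needs >= 2 records")
            means[cls] = group.mean(axis=0)
            cov = np.cov(group, rowvar=False)
            covs[cls] = np.atleast_2d(cov)
            pooled_num += covs[cls] * (len(group) - 1)
            pooled_dof += len(group) - 1
        if self.covariance == "pooled":
            pooled = pooled_num / pooled_dof
            covs = {cls: pooled.copy() for cls in self.classes_}
        elif self.covariance == "diagonal":
            covs = {cls: np.diag(np.diag(c)) for cls, c in covs.items()}
        for cls, cov in covs.items():
            if not self._is_pd(cov):
                warnings.warn(
                    f"singular covariance for group {cls!r}; falling back to diagonal",
                    stacklevel=2,
                )
                covs[cls] = np.diag(np.maximum(np.diag(cov), 1e-12))
        self.means_ = means
        self.covariances_ = covs
        return self

    @staticmethod
    def _is_pd(cov: np.ndarray) -> bool:
        try:
            linalg.cholesky(cov, lower=True)
            return True
        except linalg.LinAlgError:
            return False

    def to_gaussian_model(self) -> GaussianModel:
        return GaussianModel(
            means={k: np.asarray(v) for k, v in self.means_.items()},
            covariances={k: np.asarray(v) for k, v in self.covariances_.items()},
            markers=self.marker_names_,
        )

    def likelihood_ratio(self, X, affected: str, unaffected: str | None = None):
        """Marker LR for hypothesis ``affected`` against the unaffected group."""
        unaffected = self.unaffected_label if unaffected is None else unaffected
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return marker_lr(
            np.asarray(X, dtype=float),
            (self.means_[affected], self.covariances_[affected]),
            (self.means_[unaffected], self.covariances_[unaffected]),
        )

    def predict_proba_prior(self, X, prior, affected: str):
        """Posterior probabilities given external per-record prior risks."""
        return posterior_risk(prior, self.likelihood_ratio(X, affected))


def fit_gaussian_model(
    X, y, covariance: str = "full", unaffected_label: str = "none"
) -> GaussianModel:
    """Functional wrapper: fit and return the :class:`GaussianModel` parameters."""
    est = GaussianRiskModel(covariance=covariance, unaffected_label=unaffected_label)
    est.fit(X, y)
    return est.to_gaussian_model()


@dataclass(frozen=True)
class RiskResult:
    """Prior and posterior early/late risks for one pregnancy."""

    prior_early: float
    prior_late: float
    posterior_early: float
    posterior_late: float
    screen_positive_early: bool = field(default=False)
    screen_positive_late: bool = field(default=False)

    @property
    def formatted(self) -> dict[str, str]:
        return {
            "prior_early": format_risk(self.prior_early),
            "prior_late": format_risk(self.prior_late),
            "posterior_early": format_risk(self.posterior_early),
            "posterior_late": format_risk(self.posterior_late),
        }
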
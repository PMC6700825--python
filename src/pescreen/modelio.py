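"""Versioned YAML serialization of the fitted/configured risk model bundle.

A *risk model bundle* is everything needed to score a pregnancy: the median
model (expected medians + covariate adjustments), the prior LR model, and the
marker Gaussian parameters.  The file format is human-readable YAML with a
schema version field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .mom import MarkerMedianModel, MedianModel
from .risk import GaussianModel, PriorModel

__all__ = ["RiskModelBundle", "save_bundle", "load_bundle"]

SCHEMA_VERSION = 1


class RiskModelBundle:
    """Container for (median_model, prior_model, gaussian_model)."""

    def __init__(
        self,
        median_model: MedianModel,
        prior_model: PriorModel,
        gaussian_model: Optional[GaussianModel] = None,
    ):
        self.median_model = median_model
        self.prior_model = prior_model
        self.gaussian_model = gaussian_model


def _median_to_dict(model: MedianModel) -> dict:
    return {
        "reference_weight": model.reference_weight,
        "ga_window": list(model.ga_window),
        "truncation": list(model.truncation),
        "markers": {
            name: {
                "intercept": spec.intercept,
                "slope": spec.slope,
                "weight_slope": spec.weight_slope,
                "ethnicity_factors": dict(spec.ethnicity_factors),
                "smoking_factor": spec.smoking_factor,
            }
            for name, spec in model.markers.items()
        },
    }


def _median_from_dict(data: dict) -> MedianModel:
    return MedianModel(
        markers={
            name: MarkerMedianModel(
                intercept=spec["intercept"],
                slope=spec["slope"],
                weight_slope=spec.get("weight_slope", 0.0),
                ethnicity_factors=spec.get("ethnicity_factors", {"chinese": 1.0}),
                smoking_factor=spec.get("smoking_factor", 1.0),
            )
            for name, spec in data["markers"].items()
        },
        reference_weight=data["reference_weight"],
        ga_window=tuple(data["ga_window"]),
        truncation=tuple(data["truncation"]),
    )


def _prior_to_dict(model: PriorModel) -> dict:
    return {
        "baseline": dict(model.baseline),
        "lr_tables": {
            h: {f: dict(levels) for f, levels in table.items()}
            for h, table in model.lr_tables.items()
        },
        "bmi_bands": [[label, lo, "inf" if np.isinf(hi) else hi] for label, lo, hi in model.bmi_bands],
    }


def _prior_from_dict(data: dict) -> PriorModel:
    bands = tuple(
        (label, float(lo), np.inf if hi == "inf" else float(hi))
        for label, lo, hi in data["bmi_bands"]
    )
    return PriorModel(
        baseline=data["baseline"], lr_tables=data["lr_tables"], bmi_bands=bands
    )


def _gaussian_to_dict(model: GaussianModel) -> dict:
    return {
        "markers": list(model.markers),
        "means": {k: np.asarray(v).tolist() for k, v in model.means.items()},
        "covariances": {k: np.asarray(v).tolist() for k, v in model.covariances.items()},
    }


def _gaussian_from_dict(data: dict) -> GaussianModel:
    return GaussianModel(
        means={k: np.asarray(v, dtype=float) for k, v in data["means"].items()},
        covariances={k: np.asarray(v, dtype=float) for k, v in data["covariances"].items()},
        markers=tuple(data["markers"]),
    )


def save_bundle(bundle: RiskModelBundle, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "median_model": _median_to_dict(bundle.median_model),
        "prior_model": _prior_to_dict(bundle.prior_model),
        "gaussian_model": (
            _gaussian_to_dict(bundle.gaussian_model) if bundle.gaussian_model else None
        ),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_bundle(path: str | Path) -> RiskModelBundle:
    doc = yaml.safe_load(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    return RiskModelBundle(
        median_model=_median_from_dict(doc["median_model"]),
        prior_model=_prior_from_dict(doc["prior_model"]),
        gaussian_model=(
            _gaussian_from_dict(doc["gaussian_model"]) if doc.get("gaussian_model") else None
        ),
    )
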
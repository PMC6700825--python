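"""End-to-end pipeline: simulate -> fit -> score -> evaluate, with manifest.

A single YAML config drives all stages; every random stage takes an explicit
seed, so a given (config, seed) pair reproduces the run's report files
byte-for-byte.  Stage outputs land in a run directory together with a JSON
manifest recording the config hash, seeds, package version, output hashes and
timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, params
from .bp import final_map, parse_bp_series
from .cohort import (
    SchemaError,
    pe_status_frame,
    read_cohort_frame,
    write_cohort,
)
from .evaluate import (
    best_cutoff,
    compare_auc,
    fixed_fpr_table,
    roc_auc,
    summarize_group_moms,
)
from .modelio import RiskModelBundle, save_bundle
from .mom import MoMTransformer
from .risk import (
    GaussianRiskModel,
    format_risk,
    posterior_risk,
    prior_risk_frame,
    screen_positive,
)
from .simulate import default_config, generate

__all__ = [
    "run_pipeline",
    "score_cohort",
    "compute_map_frame",
    "mom_input_frame",
    "import_supplementary",
    "PipelineError",
]

log = logging.getLogger("pescreen")

REQUIRED_SECTIONS = ("simulate", "model", "evaluate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def compute_map_frame(frame: pd.DataFrame) -> pd.Series:
    """Final MAP (mmHg) per row from the encoded per-arm BP series."""
    values = np.empty(len(frame))
    for i, (left, right) in enumerate(zip(frame["bp_left"], frame["bp_right"])):
        result = final_map(
            parse_bp_series(left, "left"), parse_bp_series(right, "right")
        )
        values[i] = result.final_map
    return pd.Series(values, index=frame.index, name="map")


def mom_input_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Assemble the MoM-engine input columns from a cohort frame."""
    return pd.DataFrame(
        {
            "map": compute_map_frame(frame),
            "plgf": frame["plgf_pg_ml"].astype(float),
            "pappa": frame["pappa_mu_l"].astype(float),
            "ga_days": frame["ga_screening_days"].astype(float),
            "weight": frame["weight_kg"].astype(float),
            "ethnicity": frame["ethnicity"].astype(str),
            "smoking": frame["smoking"].astype(float),
        }
    )


def score_cohort(
    frame: pd.DataFrame,
    bundle: RiskModelBundle,
    cutoffs: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-pregnancy prior and posterior risks (both horizons).

    Requires a bundle with a fitted Gaussian model.  Returns a frame with
    probabilities, "1 in N" strings and screen-positive flags.
    """
    if bundle.gaussian_model is None:
        raise PipelineError("score: model bundle has no fitted Gaussian model")
    cutoffs = dict(cutoffs or {"early": 20, "late": 20})
    moms = MoMTransformer(median_model=bundle.median_model).fit(None).transform(
        mom_input_frame(frame)
    )
    X = moms[["log10_mom_map", "log10_mom_plgf", "log10_mom_pappa"]].to_numpy()
    gm = bundle.gaussian_model
    est = GaussianRiskModel()
    est.means_ = dict(gm.means)
    est.covariances_ = dict(gm.covariances)
    est.marker_names_ = gm.markers
    est.classes_ = tuple(gm.means)
    out = pd.DataFrame({"id": frame["id"].astype(str)})
    for horizon in ("early", "late"):
        prior = prior_risk_frame(frame, bundle.prior_model, horizon)
        lr = est.likelihood_ratio(X, affected=horizon, unaffected="none")
        post = posterior_risk(prior, lr)
        out[f"prior_{horizon}"] = prior
        out[f"posterior_{horizon}"] = post
        out[f"prior_{horizon}_fmt"] = [format_risk(p) for p in prior]
        out[f"posterior_{horizon}_fmt"] = [format_risk(p) for p in post]
        out[f"screen_positive_{horizon}"] = screen_positive(post, cutoffs[horizon])
    for col in moms.columns:
        out[col] = moms[col].to_numpy()
    return out


def _validate_config(config: Mapping) -> None:
    missing = [s for s in REQUIRED_SECTIONS if s not in config]
    if missing:
        raise PipelineError(f"config: missing required section(s) {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run simulate -> fit -> score -> evaluate; returns the run directory."""
    if not isinstance(config, Mapping):
        config = yaml.safe_load(Path(config).read_text())
    _validate_config(config)
    out = Path(out_dir or config.get("output", "pescreen_run"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    try:
        # --- simulate ----------------------------------------------------
        t0 = time.time()
        sim_cfg = config["simulate"]
        seed = int(config.get("seed", 0))
        gen_config = default_config(
            n_total=sim_cfg.get("n_total"), seed=seed
        )
        if not sim_cfg.get("fixed_counts", True):
            gen_config = type(gen_config)(
                **{**gen_config.__dict__, "mode": "probabilistic"}
            )
        cohort = generate(gen_config)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        manifest["stages"]["simulate"] = {"seed": seed, "n": len(cohort), "s": time.time() - t0}
        log.info("simulate: %d pregnancies", len(cohort))

        # --- fit ---------------------------------------------------------
        t0 = time.time()
        frame = read_cohort_frame(cohort_path, require_outcomes=True)
        status = pe_status_frame(frame)
        model_cfg = config["model"]
        inputs = mom_input_frame(frame)
        if model_cfg.get("medians", "default") == "refit":
            transformer = MoMTransformer().fit(inputs, status)
        else:
            transformer = MoMTransformer(median_model=gen_config.median_model).fit(None)
        moms = transformer.transform(inputs)
        X = moms[["log10_mom_map", "log10_mom_plgf", "log10_mom_pappa"]]
        est = GaussianRiskModel(covariance=model_cfg.get("covariance", "full"))
        est.fit(X, status)
        bundle = RiskModelBundle(
            median_model=transformer.median_model_,
            prior_model=params.default_prior_model(),
            gaussian_model=est.to_gaussian_model(),
        )
        model_path = out / "model.yaml"
        save_bundle(bundle, model_path)
        manifest["stages"]["fit"] = {"s": time.time() - t0}

        # --- score -------------------------------------------------------
        t0 = time.time()
        eval_cfg = config["evaluate"]
        risks = score_cohort(frame, bundle, cutoffs=eval_cfg.get("cutoffs"))
        risks_path = out / "risks.csv"
        risks.to_csv(risks_path, index=False)
        manifest["stages"]["score"] = {"s": time.time() - t0}

        # --- evaluate ----------------------------------------------------
        t0 = time.time()
        risks = risks.assign(pe_status=status.to_numpy(), sga=frame["sga"].to_numpy())
        summary = summarize_group_moms(risks)
        summary.to_csv(out / "marker_summary.csv", index=False)
        delivery = frame["ga_delivery_wk"].to_numpy(float)
        sga = frame["sga"].fillna(0).to_numpy(float) > 0
        pe = status.to_numpy()
        auc_rows = []
        for horizon in ("early", "late"):
            labels = pe == horizon
            post = risks[f"posterior_{horizon}"].to_numpy()
            prior = risks[f"prior_{horizon}"].to_numpy()
            roc = roc_auc(post, labels)
            roc_prior = roc_auc(prior, labels)
            _, p_cmp = compare_auc(post, prior, labels)
            cut = best_cutoff(roc)
            auc_rows.append(
                {
                    "horizon": horizon,
                    "risk": "posterior",
                    "auc": roc.auc,
                    "auc_ci_lo": roc.auc_ci[0],
                    "auc_ci_hi": roc.auc_ci[1],
                    "best_cutoff": format_risk(cut.threshold)
                    if 0 < cut.threshold < 1
                    else "NA",
                    "dr_pct": cut.dr_pct,
                    "fpr_pct": cut.fpr_pct,
                    "p_vs_prior": p_cmp,
                }
            )
            auc_rows.append(
                {
                    "horizon": horizon,
                    "risk": "prior",
                    "auc": roc_prior.auc,
                    "auc_ci_lo": roc_prior.auc_ci[0],
                    "auc_ci_hi": roc_prior.auc_ci[1],
                    "best_cutoff": "NA",
                    "dr_pct": np.nan,
                    "fpr_pct": np.nan,
                    "p_vs_prior": np.nan,
                }
            )
            pd.DataFrame(
                {
                    "threshold": roc.thresholds,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                }
            ).to_csv(out / f"roc_{horizon}.csv", index=False)
            early_delivery = delivery < 34.0
            horizon_mask = early_delivery if horizon == "early" else ~early_delivery
            subgroups = {
                f"{horizon}_pe": labels,
                f"{horizon}_pe_with_sga": labels & sga,
                f"{horizon}_pe_with_aga": labels & ~sga,
                f"{horizon}_sga": sga & horizon_mask,
                f"{horizon}_sga_without_pe": sga & horizon_mask & (pe == "none"),
            }
            table = fixed_fpr_table(
                post,
                subgroups,
                unaffected=(pe == "none") & ~sga,
                fpr_targets=eval_cfg.get("fpr_targets", (5.0, 10.0, 15.0)),
            )
            table.to_csv(out / f"fixed_fpr_{horizon}.csv", index=False)
        pd.DataFrame(auc_rows).to_csv(out / "auc_report.csv", index=False)
        manifest["stages"]["evaluate"] = {"s": time.time() - t0}
    except (ValueError, KeyError, SchemaError) as exc:
        log.removeHandler(handler)
        raise PipelineError(f"pipeline failed: {exc}") from exc
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)

    for artifact in sorted(out.glob("*.csv")) + [out / "model.yaml"]:
        manifest["outputs"][artifact.name] = _sha256(artifact)
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def import_supplementary(
    path: str | Path,
    mapping: Mapping[str, str],
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Load a recorded-risk spreadsheet (per-participant marker results and
    software risk outputs) into a scored-cohort frame.

    ``mapping`` maps canonical names (``posterior_early``, ``posterior_late``,
    optionally ``id``, ``pe_status``, ``ga_delivery_wk``, ``sga``, marker MoM
    columns...) to the spreadsheet's header names, since supplementary layouts
    vary.  Degrades to score-only mode when no outcome columns are mapped.
    """
    path = Path(path)
    if path.suffix.lower() == ".xls":
        raise ValueError(
            "legacy .xls is not supported; convert to .xlsx or .csv first"
        )
    if path.suffix.lower() == ".csv":
        raw = pd.read_csv(path)
    else:
        raw = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    required = ["posterior_early", "posterior_late"]
    missing = [k for k in required if k not in mapping]
    if missing:
        raise SchemaError(f"column mapping must provide {missing}")
    unmapped = [v for v in mapping.values() if v not in raw.columns]
    if unmapped:
        raise SchemaError(
            f"mapped column(s) {unmapped} not in spreadsheet; available: {list(raw.columns)}"
        )
    out = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    if "id" not in out.columns:
        out.insert(0, "id", [f"R{i + 1:05d}" for i in range(len(out))])
    has_outcomes = "pe_status" in out.columns
    out.attrs["score_only"] = not has_outcomes
    return out
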
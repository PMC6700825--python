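"""Synthetic screening-cohort generator with the study's statistical structure.

Each generated pregnancy gets an outcome group, a (MAP, PLGF, PAPP-A) log10
MoM triple drawn from that group's Gaussian, maternal characteristics drawn
from published medians/IQRs (PE groups shifted as observed), and raw data
back-computed so the analysis pipeline closes exactly:

* serum concentrations = MoM x expected median x covariate adjustment, so the
  MoM engine recovers the drawn MoM through the shipped median model;
* per-arm blood-pressure series are synthesized so the measurement-protocol
  module recovers the intended final MAP;
* outcome fields (hypertension onset, proteinuria, delivery GA) are written
  so the PE classification rule reproduces the group labels;
* SGA rows receive birth weights below the 10th-percentile chart, AGA rows
  above it.

Group IQRs are converted to log-scale standard deviations by the normal
quantile spacing of quartiles, sigma = log10(q3/q1) / (2 * 0.6745...).

Marker correlations are not published; the default covariances are diagonal,
with an optional per-group correlation block in the config.  Because the
published "unaffected by PE" row is a mixture of truly unaffected and
SGA-without-PE pregnancies, the bulk-unaffected means are calibrated (at
config construction) so that the generated mixture reproduces the published
row medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import params
from .cohort import DEFAULT_P10_TABLE, GA_WINDOW_DAYS, PercentileTable
from .mom import MedianModel, _adjustment_factor, expected_median

__all__ = [
    "GeneratorConfig",
    "iqr_to_sigma",
    "default_config",
    "generate",
    "generate_training_test_pair",
    "GROUPS",
]

#: Outcome groups; PE groups carry the early/late and SGA labels jointly.
GROUPS = (
    "early_pe_sga",
    "early_pe_aga",
    "late_pe_sga",
    "late_pe_aga",
    "sga_no_pe",
    "unaffected",
)

_QUARTILE_SPACING = 2.0 * norm.ppf(0.75)  # ~1.349 standard deviations


def iqr_to_sigma(q1: float, q3: float) -> float:
    """Log10-scale SD implied by a lognormal interquartile range."""
    if not 0.0 < q1 < q3:
        raise ValueError(f"need 0 < q1 < q3, got ({q1}, {q3})")
    return float(np.log10(q3 / q1) / _QUARTILE_SPACING)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator (defaults = the study conditions)."""

    n_total: int
    counts: Mapping[str, int]  # group -> count (fixed mode) / weight (probabilistic)
    marker_params: Mapping[str, Mapping[str, tuple[float, float]]]  # group -> marker -> (mu, sigma), log10 MoM
    median_model: MedianModel
    maternal: Mapping[str, Mapping[str, object]] = field(
        default_factory=lambda: params.MATERNAL_STATS
    )
    correlations: Optional[Mapping[str, np.ndarray]] = None  # group -> 3x3 corr
    truncation: tuple[float, float] = (-1.0, 1.0)
    mode: str = "fixed"  # "fixed" | "probabilistic"
    p10_table: PercentileTable = DEFAULT_P10_TABLE
    seed: int = 20160001

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) in counts: {sorted(unknown)}")
        if sum(self.counts.values()) > self.n_total:
            raise ValueError(
                f"group counts sum to {sum(self.counts.values())} > n_total {self.n_total}"
            )
        if self.mode not in ("fixed", "probabilistic"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _calibrated_unaffected_means(
    counts: Mapping[str, int]
) -> dict[str, tuple[float, float]]:
    """Bulk-unaffected (mu, sigma) solved so the PE-unaffected *mixture*
    (bulk + SGA-without-PE) reproduces the published unaffected-row medians."""
    n_bulk = counts.get("unaffected", 0)
    n_sga = counts.get("sga_no_pe", 0)
    out = {}
    for marker, (med, q1, q3) in params.GROUP_MOM_STATS["unaffected"].items():
        sigma = iqr_to_sigma(q1, q3)
        target = np.log10(med)
        if n_sga == 0 or n_bulk == 0:
            out[marker] = (float(target), sigma)
            continue
        s_med, s_q1, s_q3 = params.GROUP_MOM_STATS["sga_no_pe"][marker]
        s_sigma = iqr_to_sigma(s_q1, s_q3)
        frac_sga_below = norm.cdf((target - np.log10(s_med)) / s_sigma)
        q = (0.5 * (n_bulk + n_sga) - n_sga * frac_sga_below) / n_bulk
        q = float(np.clip(q, 1e-6, 1 - 1e-6))
        mu = target - sigma * norm.ppf(q)
        out[marker] = (float(mu), sigma)
    return out


def _group_marker_params(
    counts: Mapping[str, int]
) -> dict[str, dict[str, tuple[float, float]]]:
    stats_key = {
        "early_pe_sga": "early_pe",
        "early_pe_aga": "early_pe",
        "late_pe_sga": "late_pe",
        "late_pe_aga": "late_pe",
        "sga_no_pe": "sga_no_pe",
    }
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for group, key in stats_key.items():
        out[group] = {
            marker: (float(np.log10(med)), iqr_to_sigma(q1, q3))
            for marker, (med, q1, q3) in params.GROUP_MOM_STATS[key].items()
        }
    out["unaffected"] = _calibrated_unaffected_means(counts)
    return out


def default_config(n_total: int | None = None, seed: int = 20160001) -> GeneratorConfig:
    """The default study-condition configuration (3,270 pregnancies, fixed
    outcome counts).  Passing ``n_total`` scales every group count
    proportionally (at least one record per nonempty group)."""
    counts = dict(params.OUTCOME_COUNTS)
    base_total = sum(counts.values())
    if n_total is None:
        n_total = base_total
    elif n_total != base_total:
        scale = n_total / base_total
        scaled = {
            g: max(1, int(round(c * scale))) for g, c in counts.items() if g != "unaffected"
        }
        scaled["unaffected"] = n_total - sum(scaled.values())
        if scaled["unaffected"] < 0:
            raise ValueError(f"n_total {n_total} too small for the outcome flow")
        counts = scaled
    return GeneratorConfig(
        n_total=n_total,
        counts=counts,
        marker_params=_group_marker_params(counts),
        median_model=params.default_median_model(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _normal(rng, triple, size, lo=None, hi=None):
    med, q1, q3 = triple
    sigma = (q3 - q1) / _QUARTILE_SPACING
    draw = rng.normal(med, sigma, size)
    return np.clip(draw, lo, hi)


def _lognormal(rng, triple, size, lo=None, hi=None):
    med, q1, q3 = triple
    sigma = iqr_to_sigma(q1, q3)
    draw = 10.0 ** rng.normal(np.log10(med), sigma, size)
    return np.clip(draw, lo, hi)


def _draw_group_labels(rng, config: GeneratorConfig) -> np.ndarray:
    counts = dict(config.counts)
    counts["unaffected"] = counts.get("unaffected", 0) + (
        config.n_total - sum(counts.values())
    )
    if config.mode == "fixed":
        labels = np.concatenate(
            [np.repeat(g, counts.get(g, 0)) for g in GROUPS]
        )
    else:
        probs = np.array([counts.get(g, 0) for g in GROUPS], dtype=float)
        labels = rng.choice(GROUPS, size=config.n_total, p=probs / probs.sum())
    return rng.permutation(labels)


def _draw_log_moms(rng, config: GeneratorConfig, groups: np.ndarray) -> np.ndarray:
    """(n, 3) log10 MoM array in marker order (map, plgf, pappa)."""
    markers = ("map", "plgf", "pappa")
    out = np.empty((len(groups), 3))
    for group in GROUPS:
        mask = groups == group
        if not mask.any():
            continue
        mus = np.array([config.marker_params[group][m][0] for m in markers])
        sigmas = np.array([config.marker_params[group][m][1] for m in markers])
        cov = np.diag(sigmas**2)
        if config.correlations and group in config.correlations:
            corr = np.asarray(config.correlations[group], dtype=float)
            cov = np.outer(sigmas, sigmas) * corr
        out[mask] = rng.multivariate_normal(mus, cov, size=int(mask.sum()))
    lo, hi = config.truncation
    return np.clip(out, lo, hi)


def _synthesize_bp(rng, map_target: np.ndarray) -> tuple[list[str], list[str]]:
    """Per-arm reading strings whose protocol MAP equals ``map_target``.

    The final two readings of the higher arm straddle the target MAP
    symmetrically (mean exactly the target, jitter within the stability
    bounds); the other arm sits slightly lower, and a discarded settling
    reading precedes the stable pair.
    """
    n = len(map_target)
    pulse = np.clip(rng.normal(45.0, 5.0, n), 30.0, 60.0)
    jitter = rng.uniform(0.2, 1.0, n)
    settle = rng.uniform(3.0, 8.0, n)
    offset = rng.uniform(0.5, 4.0, n)  # lower arm deficit
    left_high = rng.random(n) < 0.5

    def arm_strings(arm_map: np.ndarray) -> list[str]:
        out = []
        for m, pp, j, s0 in zip(arm_map, pulse, jitter, settle):
            maps = (m + s0, m + j, m - j)
            readings = [(mm + 2.0 * pp / 3.0, mm - pp / 3.0) for mm in maps]
            out.append(";".join(f"{s:.10g}/{d:.10g}" for s, d in readings))
        return out

    high = arm_strings(map_target)
    low = arm_strings(map_target - offset)
    left = [h if hl else l for h, l, hl in zip(high, low, left_high)]
    right = [l if hl else h for h, l, hl in zip(high, low, left_high)]
    return left, right


def generate(
    config: GeneratorConfig,
    seed: int | None = None,
    return_latent: bool = False,
    id_prefix: str = "P",
):
    """Generate a cohort DataFrame in the standard CSV schema.

    Deterministic given ``seed`` (defaults to ``config.seed``).  With
    ``return_latent`` also returns a frame of the drawn group labels, MoM
    triples and target MAPs for closure testing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_total
    groups = _draw_group_labels(rng, config)
    is_pe = np.isin(groups, ("early_pe_sga", "early_pe_aga", "late_pe_sga", "late_pe_aga"))
    family = np.where(is_pe, "pe", "non_pe")

    cols: dict[str, np.ndarray | list] = {}
    cols["id"] = [f"{id_prefix}{i + 1:05d}" for i in range(n)]

    # --- maternal characteristics, drawn per PE family -------------------
    def by_family(key, sampler, **kw):
        out = np.empty(n)
        for fam in ("non_pe", "pe"):
            mask = family == fam
            if mask.any():
                out[mask] = sampler(rng, config.maternal[fam][key], int(mask.sum()), **kw)
        return out

    cols["maternal_age"] = np.round(by_family("maternal_age", _normal, lo=18, hi=46), 1)
    cols["weight_kg"] = np.round(by_family("weight_kg", _lognormal, lo=35, hi=120), 2)
    cols["height_cm"] = np.round(by_family("height_cm", _normal, lo=140, hi=185), 2)
    cols["crl_mm"] = np.round(by_family("crl_mm", _normal, lo=45, hi=84), 1)
    ga_days = np.rint(
        by_family("ga_screening_days", _normal, lo=GA_WINDOW_DAYS[0], hi=GA_WINDOW_DAYS[1])
    ).astype(int)
    cols["ga_screening_days"] = ga_days

    def bernoulli(rate_key):
        p = np.array([config.maternal[f][rate_key] for f in family], dtype=float)
        return (rng.random(n) < p).astype(int)

    cols["smoking"] = bernoulli("smoking_rate")
    cols["chronic_hypertension"] = bernoulli("chronic_htn_rate")
    nulliparous = bernoulli("nulliparous_rate").astype(bool)
    cols["parity"] = np.where(nulliparous, "nulliparous", "parous")
    prior_pe = bernoulli("prior_pe_rate_parous").astype(bool) & ~nulliparous
    cols["prior_pe_history"] = prior_pe.astype(int)
    cols["conception"] = np.where(bernoulli("ivf_rate") > 0, "ivf", "spontaneous")
    cols["ethnicity"] = np.repeat("chinese", n)

    # --- markers ---------------------------------------------------------
    log_moms = _draw_log_moms(rng, config, groups)
    mom_map, mom_plgf, mom_pappa = (10.0**log_moms[:, i] for i in range(3))
    model = config.median_model
    map_target = mom_map * expected_median(model, "map", ga_days)
    plgf_adj = _adjustment_factor(
        model, "plgf", cols["weight_kg"], cols["ethnicity"], cols["smoking"]
    )
    pappa_adj = _adjustment_factor(
        model, "pappa", cols["weight_kg"], cols["ethnicity"], cols["smoking"]
    )
    cols["plgf_pg_ml"] = mom_plgf * expected_median(model, "plgf", ga_days) * plgf_adj
    cols["pappa_mu_l"] = mom_pappa * expected_median(model, "pappa", ga_days) * pappa_adj
    cols["bp_left"], cols["bp_right"] = _synthesize_bp(rng, map_target)

    # --- outcomes --------------------------------------------------------
    delivery = np.empty(n)
    early_mask = np.isin(groups, ("early_pe_sga", "early_pe_aga"))
    late_mask = np.isin(groups, ("late_pe_sga", "late_pe_aga"))
    sga_only = groups == "sga_no_pe"
    unaff = groups == "unaffected"
    delivery[early_mask] = np.clip(rng.normal(32.0, 1.5, int(early_mask.sum())), 26.0, 33.85)
    delivery[late_mask] = _normal(
        rng, config.maternal["pe"]["ga_delivery_wk"], int(late_mask.sum()), lo=34.0, hi=41.5
    )
    # SGA without PE: a minority deliver early (<34 wk), the rest at term.
    n_sga_only = int(sga_only.sum())
    early_frac = 19.0 / 84.0
    sga_early = rng.random(n_sga_only) < early_frac
    sga_deliv = _normal(
        rng, config.maternal["non_pe"]["ga_delivery_wk"], n_sga_only, lo=34.0, hi=42.0
    )
    sga_deliv[sga_early] = np.clip(rng.normal(32.0, 1.5, int(sga_early.sum())), 28.0, 33.85)
    delivery[sga_only] = sga_deliv
    delivery[unaff] = _normal(
        rng, config.maternal["non_pe"]["ga_delivery_wk"], int(unaff.sum()), lo=34.0, hi=42.0
    )
    delivery = np.round(delivery, 1)
    cols["ga_delivery_wk"] = delivery

    sga_label = np.isin(groups, ("early_pe_sga", "late_pe_sga", "sga_no_pe"))
    cols["sga"] = sga_label.astype(int)
    p10 = np.array([config.p10_table.p10(g) for g in delivery])
    weight_draw = np.empty(n)
    for fam in ("non_pe", "pe"):
        mask = family == fam
        if mask.any():
            weight_draw[mask] = _normal(
                rng, config.maternal[fam]["birth_weight_g"], int(mask.sum()), lo=600, hi=4800
            )
    birth_weight = np.where(
        sga_label,
        p10 * rng.uniform(0.75, 0.97, n),  # strictly below the 10th percentile
        np.maximum(weight_draw, p10 * 1.02),
    )
    cols["birth_weight_g"] = np.round(birth_weight, 0)

    onset = np.full(n, np.nan)
    onset[is_pe] = np.clip(
        delivery[is_pe] - rng.uniform(3.0, 10.0, int(is_pe.sum())), 20.5, None
    )
    # A sliver of gestational hypertension without proteinuria among non-PE.
    gest_htn = (~is_pe) & (rng.random(n) < 0.01)
    onset[gest_htn] = np.minimum(rng.uniform(30.0, 39.0, n)[gest_htn], delivery[gest_htn] - 0.5)
    cols["hypertension_onset_ga_wk"] = np.round(onset, 1)
    cols["proteinuria"] = is_pe.astype(int)

    from .cohort import MARKER_COLUMNS, MATERNAL_COLUMNS, OUTCOME_COLUMNS

    frame = pd.DataFrame(cols)[MATERNAL_COLUMNS + MARKER_COLUMNS + OUTCOME_COLUMNS]
    if not return_latent:
        return frame
    latent = pd.DataFrame(
        {
            "id": cols["id"],
            "group": groups,
            "log10_mom_map": log_moms[:, 0],
            "log10_mom_plgf": log_moms[:, 1],
            "log10_mom_pappa": log_moms[:, 2],
            "mom_map": mom_map,
            "mom_plgf": mom_plgf,
            "mom_pappa": mom_pappa,
            "map_target": map_target,
        }
    )
    return frame, latent


def generate_training_test_pair(
    config: GeneratorConfig, split_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two independent cohorts from one config (disjoint id namespaces)."""
    seeds = np.random.SeedSequence(split_seed).generate_state(2)
    train = generate(config, seed=int(seeds[0]), id_prefix="TR")
    test = generate(config, seed=int(seeds[1]), id_prefix="TE")
    return train, test
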
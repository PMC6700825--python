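"""Cohort domain types, delimited-file I/O, validation, and outcome rules.

One row of a cohort file is one pregnancy: maternal characteristics, the raw
biophysical/biochemical markers (per-arm blood-pressure series, serum PLGF and
PAPP-A), and — when follow-up is available — the pregnancy outcome.

Outcome rules
-------------
* Preeclampsia (PE): new-onset hypertension after 20 completed weeks together
  with proteinuria; classified *early* when delivery occurs before 34 weeks'
  gestation and *late* at or after 34 weeks.
* SGA (small-for-gestational-age): birth weight strictly below the 10th
  percentile for gestational age at delivery.

Adjudication of hypertension/proteinuria from raw visit data happens upstream;
this module consumes the summary fields (onset gestational age, proteinuria
flag).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bp import BPSeries, parse_bp_series

__all__ = [
    "MaternalRecord",
    "MarkerPanel",
    "OutcomeRecord",
    "PercentileTable",
    "CohortRow",
    "ReadResult",
    "SchemaError",
    "GA_WINDOW_DAYS",
    "EARLY_LATE_BOUNDARY_WEEKS",
    "DEFAULT_P10_TABLE",
    "compute_bmi",
    "classify_pe",
    "classify_sga",
    "read_cohort",
    "read_cohort_frame",
    "write_cohort",
    "pe_status_frame",
    "MATERNAL_COLUMNS",
    "MARKER_COLUMNS",
    "OUTCOME_COLUMNS",
]

#: Screening window, gestational days (11+0 to 13+6 weeks).
GA_WINDOW_DAYS = (77, 97)
#: Delivery gestational age (weeks) splitting early from late PE (and SGA).
EARLY_LATE_BOUNDARY_WEEKS = 34.0

NA_TOKEN = "NA"

MATERNAL_COLUMNS = [
    "id",
    "maternal_age",
    "weight_kg",
    "height_cm",
    "ethnicity",
    "smoking",
    "parity",
    "prior_pe_history",
    "chronic_hypertension",
    "conception",
    "ga_screening_days",
    "crl_mm",
]
MARKER_COLUMNS = ["bp_left", "bp_right", "plgf_pg_ml", "pappa_mu_l"]
OUTCOME_COLUMNS = [
    "hypertension_onset_ga_wk",
    "proteinuria",
    "ga_delivery_wk",
    "birth_weight_g",
    "sga",
]

_NUMERIC_COLUMNS = [
    "maternal_age",
    "weight_kg",
    "height_cm",
    "ga_screening_days",
    "crl_mm",
    "plgf_pg_ml",
    "pappa_mu_l",
    "hypertension_onset_ga_wk",
    "ga_delivery_wk",
    "birth_weight_g",
]
_BOOL_COLUMNS = ["smoking", "prior_pe_history", "chronic_hypertension", "proteinuria", "sga"]


class SchemaError(ValueError):
    """A required column is missing from a cohort file."""


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError(
            f"weight and height must be positive, got {weight_kg} kg, {height_cm} cm"
        )
    return weight_kg / (height_cm / 100.0) ** 2


@dataclass(frozen=True)
class MaternalRecord:
    """Demographic and history fields for one pregnancy.

    Houses the five prior-risk factors (BMI, ethnicity, parity, history of
    PE, chronic hypertension) plus the covariates used in MoM adjustment.
    """

    id: str
    age: float
    weight: float  # kg
    height: float  # cm
    ethnicity: str
    smoking: bool
    parity: str  # "nulliparous" | "parous"
    prior_pe_history: bool
    chronic_hypertension: bool
    conception: str  # "spontaneous" | "ivf"
    ga_screening: int  # days
    crl: float  # mm

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise ValueError(f"record {self.id}: nonpositive weight/height")
        if self.parity not in ("nulliparous", "parous"):
            raise ValueError(f"record {self.id}: bad parity {self.parity!r}")
        if self.conception not in ("spontaneous", "ivf"):
            raise ValueError(f"record {self.id}: bad conception {self.conception!r}")
        lo, hi = GA_WINDOW_DAYS
        if not lo <= self.ga_screening <= hi:
            raise ValueError(
                f"record {self.id}: GA at screening {self.ga_screening} d outside "
                f"window [{lo}, {hi}] d"
            )

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)


@dataclass(frozen=True)
class MarkerPanel:
    """Raw marker measurements for one pregnancy."""

    bp_left: BPSeries
    bp_right: BPSeries
    plgf: float  # pg/mL
    pappa: float  # mU/L

    def __post_init__(self) -> None:
        if self.plgf <= 0 or self.pappa <= 0:
            raise ValueError("serum concentrations must be positive")


@dataclass(frozen=True)
class OutcomeRecord:
    """Pregnancy outcome summary."""

    ga_delivery: float  # decimal weeks
    birth_weight: float  # g
    sga: bool
    hypertension_onset_ga: Optional[float] = None  # weeks; None = no hypertension
    proteinuria: bool = False

    @property
    def pe_status(self) -> str:
        return classify_pe(self.hypertension_onset_ga, self.proteinuria, self.ga_delivery)


@dataclass(frozen=True)
class CohortRow:
    maternal: MaternalRecord
    markers: MarkerPanel
    outcome: Optional[OutcomeRecord]


@dataclass(frozen=True)
class RowIssue:
    row: int  # 0-based data-row index
    id: str
    message: str


@dataclass
class ReadResult:
    records: list[CohortRow] = field(default_factory=list)
    rejects: list[RowIssue] = field(default_factory=list)


def classify_pe(
    hypertension_onset_ga: Optional[float],
    proteinuria: bool,
    ga_delivery: float,
) -> str:
    """Classify a pregnancy as ``"none"``, ``"early"`` or ``"late"`` PE.

    PE requires hypertension onset after 20 weeks together with proteinuria;
    onset at or before 20 weeks is outside the new-onset definition (chronic
    hypertension) and yields ``"none"`` with a warning.  PE deliveries before
    34 weeks are early, at or after 34 weeks late.
    """
    if hypertension_onset_ga is None or (
        isinstance(hypertension_onset_ga, float) and np.isnan(hypertension_onset_ga)
    ):
        return "none"
    if hypertension_onset_ga <= 20.0:
        warnings.warn(
            f"hypertension onset at {hypertension_onset_ga} wk is not new-onset "
            "(<=20 wk); classified as non-PE",
            stacklevel=2,
        )
        return "none"
    if not proteinuria:
        return "none"
    if ga_delivery <= 20.0:
        raise ValueError(f"delivery GA {ga_delivery} wk implausible for PE classification")
    return "early" if ga_delivery < EARLY_LATE_BOUNDARY_WEEKS else "late"


@dataclass(frozen=True)
class PercentileTable:
    """10th-percentile birth weight by gestational week at delivery.

    The national reference chart is an external resource; any two-column table
    (ga_week, p10 weight in g) with strictly increasing weights can be loaded.
    Lookups linearly interpolate between weekly rows.
    """

    ga_weeks: tuple[float, ...]
    p10_g: tuple[float, ...]

    def __post_init__(self) -> None:
        ga = np.asarray(self.ga_weeks, dtype=float)
        wt = np.asarray(self.p10_g, dtype=float)
        if ga.size < 2:
            raise ValueError("percentile table needs at least two rows")
        if not np.all(np.diff(ga) > 0):
            raise ValueError("ga_week column must be strictly increasing")
        if not np.all(np.diff(wt) > 0):
            raise ValueError("p10 weights must be strictly increasing in GA")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PercentileTable":
        frame = pd.read_csv(path)
        for col in ("ga_week", "p10_g"):
            if col not in frame.columns:
                raise SchemaError(f"percentile table missing column {col!r}")
        return cls(tuple(frame["ga_week"]), tuple(frame["p10_g"]))

    def p10(self, ga_delivery_wk: float) -> float:
        lo, hi = self.ga_weeks[0], self.ga_weeks[-1]
        if not lo <= ga_delivery_wk <= hi:
            raise ValueError(
                f"delivery GA {ga_delivery_wk} wk outside table range [{lo}, {hi}] wk"
            )
        return float(np.interp(ga_delivery_wk, self.ga_weeks, self.p10_g))


# Synthetic sex-agnostic default p10 chart (smooth plausible curve; the real
# population reference is an external publication and should be supplied by
# the user for clinical work).
DEFAULT_P10_TABLE = PercentileTable(
    ga_weeks=(24, 26, 28, 30, 32, 34, 36, 37, 38, 39, 40, 41, 42),
    p10_g=(600, 760, 960, 1210, 1510, 1860, 2260, 2460, 2650, 2800, 2930, 3020, 3080),
)


def classify_sga(
    birth_weight_g: float,
    ga_delivery_wk: float,
    table: PercentileTable = DEFAULT_P10_TABLE,
) -> bool:
    """True iff birth weight is strictly below the interpolated 10th percentile."""
    return birth_weight_g < table.p10(ga_delivery_wk)


# ---------------------------------------------------------------------------
# Cohort file I/O
# ---------------------------------------------------------------------------

def read_cohort_frame(
    path: str | Path | io.StringIO, require_outcomes: bool = False
) -> pd.DataFrame:
    """Read a cohort CSV into a typed DataFrame (no row-level validation).

    Missing values use the token ``NA``.  Outcome columns are optional unless
    ``require_outcomes``; when absent they are added as all-missing.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[NA_TOKEN, ""])
    required = MATERNAL_COLUMNS + MARKER_COLUMNS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {missing}")
    if require_outcomes:
        missing_out = [c for c in OUTCOME_COLUMNS if c not in frame.columns]
        if missing_out:
            raise SchemaError(f"cohort file missing outcome column(s): {missing_out}")
    for col in OUTCOME_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    for col in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r}, data row {row}"
            )
        frame[col] = converted
    for col in _BOOL_COLUMNS:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame


def _row_to_records(row: pd.Series) -> CohortRow:
    maternal = MaternalRecord(
        id=str(row["id"]),
        age=float(row["maternal_age"]),
        weight=float(row["weight_kg"]),
        height=float(row["height_cm"]),
        ethnicity=str(row["ethnicity"]),
        smoking=bool(row["smoking"]),
        parity=str(row["parity"]),
        prior_pe_history=bool(row["prior_pe_history"]),
        chronic_hypertension=bool(row["chronic_hypertension"]),
        conception=str(row["conception"]),
        ga_screening=int(row["ga_screening_days"]),
        crl=float(row["crl_mm"]),
    )
    markers = MarkerPanel(
        bp_left=parse_bp_series(row["bp_left"], arm="left"),
        bp_right=parse_bp_series(row["bp_right"], arm="right"),
        plgf=float(row["plgf_pg_ml"]),
        pappa=float(row["pappa_mu_l"]),
    )
    outcome = None
    if pd.notna(row["ga_delivery_wk"]) and pd.notna(row["birth_weight_g"]):
        onset = row["hypertension_onset_ga_wk"]
        outcome = OutcomeRecord(
            ga_delivery=float(row["ga_delivery_wk"]),
            birth_weight=float(row["birth_weight_g"]),
            sga=bool(row["sga"]) if pd.notna(row["sga"]) else False,
            hypertension_onset_ga=float(onset) if pd.notna(onset) else None,
            proteinuria=bool(row["proteinuria"]) if pd.notna(row["proteinuria"]) else False,
        )
    return CohortRow(maternal=maternal, markers=markers, outcome=outcome)


def read_cohort(path: str | Path | io.StringIO) -> ReadResult:
    """Read and validate a cohort CSV.

    Rows violating record invariants (nonpositive weight/height, GA outside
    the screening window, malformed BP series, ...) are rejected with a
    row-level diagnostic rather than aborting the read.
    """
    frame = read_cohort_frame(path)
    result = ReadResult()
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            result.records.append(_row_to_records(row))
        except (ValueError, TypeError) as exc:
            result.rejects.append(RowIssue(row=i, id=str(row.get("id", "?")), message=str(exc)))
    return result


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort DataFrame in the standard CSV dialect (NA for missing)."""
    frame.to_csv(path, index=False, na_rep=NA_TOKEN)


def pe_status_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_pe` over a cohort DataFrame."""
    onset = frame["hypertension_onset_ga_wk"].to_numpy(dtype=float)
    proteinuria = frame["proteinuria"].fillna(0).to_numpy(dtype=float) > 0
    delivery = frame["ga_delivery_wk"].to_numpy(dtype=float)
    is_pe = np.isfinite(onset) & (onset > 20.0) & proteinuria
    status = np.where(
        is_pe & (delivery < EARLY_LATE_BOUNDARY_WEEKS),
        "early",
        np.where(is_pe, "late", "none"),
    )
    return pd.Series(status, index=frame.index, name="pe_status")
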
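"""Traffic-light scoring of the nine modifiable dementia-risk behaviour domains.

Each domain classifier maps raw survey responses to a risk level (low /
medium / high, or unknown when required inputs are missing).  Levels carry
additive weights — low 0, medium 0.5, high 1 — and the nine domain weights
sum to the continuous DRP total (range 0 to 9, steps of 0.5).  Two domains
(physical activity, cognitive activity) are two-level: they are either low
or high, never medium.

Cut points:

=====================  =============================  =========================
domain                 low                            high
=====================  =============================  =========================
alcohol                abstains or ≤2 drinks/occasion >14 std drinks/week
bmi                    18 ≤ BMI < 25                  BMI ≥ 30
hypertension (mgmt)    no dx + check-ups, or managed  dx unmanaged / no checks
cholesterol (mgmt)     as hypertension                as hypertension
diabetes (mgmt)        as hypertension                as hypertension
smoking                not smoking                    weekly or more
cognitive_activity     11-item frequency sum ≥ 33     sum < 33
physical_activity      ≥ 600 MET-minutes/week         < 600
diet (MIND adherence)  score ≥ 12                     score < 7.5
=====================  =============================  =========================

Everything between low and high on a three-level domain is medium.  BMI and
MIND bands are half-open ([18, 25), [25, 30); [7.5, 12)) so no value falls
in a gap.  MET-minutes weight light / moderate / vigorous weekly minutes by
3.3 / 4 / 8.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RiskLevel",
    "DOMAINS",
    "THREE_LEVEL_DOMAINS",
    "TWO_LEVEL_DOMAINS",
    "DRPProfile",
    "score_alcohol",
    "score_bmi",
    "score_cardiometabolic",
    "score_smoking",
    "compute_met_minutes",
    "score_physical_activity",
    "score_cognitive_activity",
    "score_mind_diet",
    "assemble_drp",
    "score_dataframe",
    "SCHEMA_COLUMNS",
]

MET_WEIGHTS = {"light": 3.3, "moderate": 4.0, "vigorous": 8.0}
MET_SUFFICIENT = 600.0
COGNITIVE_SUFFICIENT = 33.0
COGNITIVE_N_ITEMS = 11
COGNITIVE_SCALE_MAX = 5
MIND_N_COMPONENTS = 14
MIND_LOW = 12.0
MIND_MEDIUM = 7.5
ALCOHOL_WEEKLY_LIMIT = 14.0
ALCOHOL_OCCASION_LIMIT = 2.0
BMI_LOW = 18.0
BMI_MEDIUM = 25.0
BMI_HIGH = 30.0


class RiskLevel(str, enum.Enum):
    """Traffic-light risk level for one behaviour domain."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    UNKNOWN = "unknown"

    @property
    def weight(self) -> float:
        """Additive contribution to the DRP total (NaN for unknown)."""
        return _WEIGHTS[self]


_WEIGHTS = {
    RiskLevel.LOW: 0.0,
    RiskLevel.MEDIUM: 0.5,
    RiskLevel.HIGH: 1.0,
    RiskLevel.UNKNOWN: float("nan"),
}

#: Canonical domain order used throughout the package.
DOMAINS = (
    "alcohol",
    "bmi",
    "hypertension",
    "cholesterol",
    "diabetes",
    "smoking",
    "cognitive_activity",
    "physical_activity",
    "diet",
)
TWO_LEVEL_DOMAINS = ("cognitive_activity", "physical_activity")
THREE_LEVEL_DOMAINS = tuple(d for d in DOMAINS if d not in TWO_LEVEL_DOMAINS)

SMOKING_CATEGORIES = ("none", "occasional", "weekly_or_more")
DIAGNOSIS_CATEGORIES = ("yes", "no", "unsure")
MANAGED_CATEGORIES = ("medically_managed", "working_toward", "unmanaged", "n/a")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or (x is pd.NA)


def score_alcohol(drinks_per_week, max_drinks_per_occasion, abstains) -> RiskLevel:
    """Classify alcohol consumption.

    High: more than 14 standard drinks per week.  Medium: within the weekly
    limit but more than 2 standard drinks on an occasion.  Low: abstaining,
    or no more than 2 drinks per occasion.
    """
    if not _is_missing(abstains) and bool(abstains):
        return RiskLevel.LOW
    if _is_missing(drinks_per_week):
        return RiskLevel.UNKNOWN
    if drinks_per_week < 0:
        raise ValueError(f"drinks_per_week must be >= 0, got {drinks_per_week}")
    if drinks_per_week > ALCOHOL_WEEKLY_LIMIT:
        return RiskLevel.HIGH
    if _is_missing(max_drinks_per_occasion):
        # weekly total alone cannot separate low from medium
        return RiskLevel.UNKNOWN
    if max_drinks_per_occasion < 0:
        raise ValueError(
            f"max_drinks_per_occasion must be >= 0, got {max_drinks_per_occasion}"
        )
    if max_drinks_per_occasion > ALCOHOL_OCCASION_LIMIT:
        return RiskLevel.MEDIUM
    return RiskLevel.LOW


def score_bmi(height, weight) -> RiskLevel:
    """Classify body-mass index (kg/m²): low [18, 25), medium [25, 30) or
    < 18, high ≥ 30."""
    if _is_missing(height) or _is_missing(weight):
        return RiskLevel.UNKNOWN
    if height <= 0 or weight <= 0:
        raise ValueError(f"height and weight must be > 0, got ({height}, {weight})")
    bmi = weight / height**2
    if bmi >= BMI_HIGH:
        return RiskLevel.HIGH
    if bmi >= BMI_MEDIUM or bmi < BMI_LOW:
        return RiskLevel.MEDIUM
    return RiskLevel.LOW


def score_cardiometabolic(diagnosis, regular_checkups, managed) -> RiskLevel:
    """Classify management of a cardiometabolic condition (applied
    identically to hypertension, cholesterol and diabetes).

    Low: no diagnosis with regular check-ups, or a diagnosis that is
    medically managed.  Medium: unsure of diagnosis but regular check-ups,
    or diagnosed with check-ups and working toward managing it.  High:
    diagnosed without check-ups or medical management, or no diagnosis and
    no check-ups.
    """
    dx_missing = _is_missing(diagnosis)
    cu_missing = _is_missing(regular_checkups)
    mg_missing = _is_missing(managed)
    if not dx_missing and diagnosis not in DIAGNOSIS_CATEGORIES:
        raise ValueError(f"unrecognised diagnosis category: {diagnosis!r}")
    if not mg_missing and managed not in MANAGED_CATEGORIES:
        raise ValueError(f"unrecognised management category: {managed!r}")
    if dx_missing:
        return RiskLevel.UNKNOWN
    checkups = None if cu_missing else bool(regular_checkups)
    managed_v = None if mg_missing else managed
    if diagnosis == "yes":
        if managed_v == "medically_managed":
            return RiskLevel.LOW
        if checkups and managed_v == "working_toward":
            return RiskLevel.MEDIUM
        if checkups is None or managed_v is None:
            return RiskLevel.UNKNOWN
        return RiskLevel.HIGH
    if checkups is None:
        return RiskLevel.UNKNOWN
    if diagnosis == "no":
        return RiskLevel.LOW if checkups else RiskLevel.HIGH
    # unsure of diagnosis
    return RiskLevel.MEDIUM if checkups else RiskLevel.UNKNOWN


def score_smoking(smoking) -> RiskLevel:
    """Classify smoking: none → low, occasional → medium, weekly or more →
    high."""
    if _is_missing(smoking):
        return RiskLevel.UNKNOWN
    if smoking not in SMOKING_CATEGORIES:
        raise ValueError(f"unrecognised smoking category: {smoking!r}")
    return {
        "none": RiskLevel.LOW,
        "occasional": RiskLevel.MEDIUM,
        "weekly_or_more": RiskLevel.HIGH,
    }[smoking]


def compute_met_minutes(light_min, moderate_min, vigorous_min) -> float:
    """Weekly MET-minutes: 3.3·light + 4·moderate + 8·vigorous.

    Returns NaN when any component is missing.
    """
    parts = (light_min, moderate_min, vigorous_min)
    if any(_is_missing(p) for p in parts):
        return float("nan")
    if any(p < 0 for p in parts):
        raise ValueError(f"activity minutes must be >= 0, got {parts}")
    return (
        MET_WEIGHTS["light"] * light_min
        + MET_WEIGHTS["moderate"] * moderate_min
        + MET_WEIGHTS["vigorous"] * vigorous_min
    )


def score_physical_activity(met_minutes) -> RiskLevel:
    """Two-level domain: ≥ 600 weekly MET-minutes → low, otherwise high."""
    if _is_missing(met_minutes):
        return RiskLevel.UNKNOWN
    if met_minutes < 0:
        raise ValueError(f"met_minutes must be >= 0, got {met_minutes}")
    return RiskLevel.LOW if met_minutes >= MET_SUFFICIENT else RiskLevel.HIGH


def score_cognitive_activity(cognitive_freq) -> RiskLevel:
    """Two-level domain scored from 11 activity-frequency codes (0–5 each,
    'several times a month' = 3); the summed score is low risk at ≥ 33."""
    freqs = list(cognitive_freq)
    if len(freqs) != COGNITIVE_N_ITEMS:
        raise ValueError(
            f"expected {COGNITIVE_N_ITEMS} cognitive-activity items, got {len(freqs)}"
        )
    if any(_is_missing(f) for f in freqs):
        return RiskLevel.UNKNOWN
    for f in freqs:
        if not (0 <= f <= COGNITIVE_SCALE_MAX):
            raise ValueError(f"cognitive frequency code out of range 0..5: {f}")
    score = float(sum(freqs))
    return RiskLevel.LOW if score >= COGNITIVE_SUFFICIENT else RiskLevel.HIGH


def score_mind_diet(mind_components) -> tuple[RiskLevel, float]:
    """Score MIND-diet adherence (14 scoreable components, wine excluded,
    each 0 / 0.5 / 1).

    Returns ``(level, adherence)``: adherence = component sum in [0, 14];
    low ≥ 12, medium [7.5, 12), high < 7.5.
    """
    comps = list(mind_components)
    if len(comps) != MIND_N_COMPONENTS:
        raise ValueError(
            f"expected {MIND_N_COMPONENTS} MIND components, got {len(comps)}"
        )
    if any(_is_missing(c) for c in comps):
        return RiskLevel.UNKNOWN, float("nan")
    for c in comps:
        if c not in (0, 0.5, 1):
            raise ValueError(f"MIND component must be 0, 0.5 or 1, got {c}")
    adherence = float(np.clip(sum(comps), 0.0, MIND_N_COMPONENTS))
    if adherence >= MIND_LOW:
        return RiskLevel.LOW, adherence
    if adherence >= MIND_MEDIUM:
        return RiskLevel.MEDIUM, adherence
    return RiskLevel.HIGH, adherence


@dataclass
class DRPProfile:
    """Nine-domain risk profile with the continuous DRP total.

    ``drp_total`` is defined only when no domain is unknown; otherwise NaN
    with ``n_unknown`` recording how many domains are unresolved.
    """

    domain_levels: dict[str, RiskLevel]
    drp_total: float = field(init=False)
    n_unknown: int = field(init=False)

    def __post_init__(self):
        if set(self.domain_levels) != set(DOMAINS):
            missing = set(DOMAINS) - set(self.domain_levels)
            extra = set(self.domain_levels) - set(DOMAINS)
            raise ValueError(
                f"profile must cover exactly the nine domains; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for d in TWO_LEVEL_DOMAINS:
            if self.domain_levels[d] is RiskLevel.MEDIUM:
                raise ValueError(f"{d} is a two-level domain and cannot be medium")
        levels = list(self.domain_levels.values())
        self.n_unknown = sum(1 for lv in levels if lv is RiskLevel.UNKNOWN)
        if self.n_unknown:
            self.drp_total = float("nan")
        else:
            self.drp_total = float(sum(lv.weight for lv in levels))


def assemble_drp(domain_levels: dict[str, RiskLevel]) -> DRPProfile:
    """Assemble the nine domain levels into a :class:`DRPProfile`."""
    return DRPProfile(dict(domain_levels))


# ---------------------------------------------------------------------------
# Vectorised scoring of a long-format survey table
# ---------------------------------------------------------------------------

MIND_COLUMNS = [f"mind_{i}" for i in range(1, MIND_N_COMPONENTS + 1)]
COGNITIVE_COLUMNS = [f"cog_{i}" for i in range(1, COGNITIVE_N_ITEMS + 1)]
CARDIO_PREFIXES = {"hypertension": "htn", "cholesterol": "chol", "diabetes": "diab"}

#: Raw behaviour columns expected in the long-format survey CSV (one row per
#: participant × wave; empty cells are missing → unknown).
SCHEMA_COLUMNS = (
    ["participant_id", "wave", "drinks_per_week", "max_drinks_per_occasion",
     "abstains", "smoking", "height_m", "weight_kg",
     "light_min", "moderate_min", "vigorous_min"]
    + MIND_COLUMNS
    + COGNITIVE_COLUMNS
    + [f"{p}_{s}" for p in CARDIO_PREFIXES.values()
       for s in ("diagnosis", "checkups", "managed")]
)

_LEVELS = np.array(["low", "medium", "high", "unknown"], dtype=object)


def _validate_nonneg(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        v = pd.to_numeric(df[c], errors="coerce")
        if (v < 0).any():
            bad = df.index[v < 0][0]
            raise ValueError(f"column {c!r} has negative value at row {bad}")


def score_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format survey table, appending per-domain ``risk_*``
    columns, ``drp_total`` and ``n_unknown``.

    Missing inputs (empty cells) propagate to level ``unknown``;
    ``drp_total`` is NaN for any row with an unknown domain.
    """
    meta = {"participant_id", "wave"}  # panel metadata, not needed to score
    missing_cols = [c for c in SCHEMA_COLUMNS
                    if c not in df.columns and c not in meta]
    if missing_cols:
        raise ValueError(f"input table is missing columns: {missing_cols}")
    out = df.copy()
    n = len(df)

    num = {c: pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
           for c in ["drinks_per_week", "max_drinks_per_occasion",
                     "height_m", "weight_kg",
                     "light_min", "moderate_min", "vigorous_min"]}
    _validate_nonneg(df, ["drinks_per_week", "max_drinks_per_occasion",
                          "light_min", "moderate_min", "vigorous_min"])
    for c in ("height_m", "weight_kg"):
        v = num[c]
        if np.any(v[~np.isnan(v)] <= 0):
            raise ValueError(f"column {c!r} must be > 0 where present")

    def _bool_series(col):
        s = df[col]
        truthy = s.isin([True, 1, "1", "true", "True", "yes"])
        falsy = s.isin([False, 0, "0", "false", "False", "no"])
        valid = truthy | falsy
        return truthy.to_numpy(), valid.to_numpy()

    levels = {}

    # alcohol
    abst, abst_known = _bool_series("abstains")
    week, occ = num["drinks_per_week"], num["max_drinks_per_occasion"]
    lv = np.full(n, "unknown", dtype=object)
    week_known, occ_known = ~np.isnan(week), ~np.isnan(occ)
    lv[week_known & (week > ALCOHOL_WEEKLY_LIMIT)] = "high"
    med = week_known & (week <= ALCOHOL_WEEKLY_LIMIT) & occ_known & (occ > ALCOHOL_OCCASION_LIMIT)
    lv[med] = "medium"
    low = week_known & (week <= ALCOHOL_WEEKLY_LIMIT) & occ_known & (occ <= ALCOHOL_OCCASION_LIMIT)
    lv[low] = "low"
    lv[abst_known & abst] = "low"
    levels["alcohol"] = lv

    # bmi
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = num["weight_kg"] / num["height_m"] ** 2
    lv = np.full(n, "unknown", dtype=object)
    known = ~np.isnan(bmi)
    lv[known & (bmi >= BMI_LOW) & (bmi < BMI_MEDIUM)] = "low"
    lv[known & ((bmi < BMI_LOW) | ((bmi >= BMI_MEDIUM) & (bmi < BMI_HIGH)))] = "medium"
    lv[known & (bmi >= BMI_HIGH)] = "high"
    levels["bmi"] = lv
    out["bmi"] = bmi

    # cardiometabolic domains
    for domain, pref in CARDIO_PREFIXES.items():
        dx = df[f"{pref}_diagnosis"].astype(object).to_numpy()
        cu, cu_known = _bool_series(f"{pref}_checkups")
        mg = df[f"{pref}_managed"].astype(object).to_numpy()
        bad_dx = pd.Series(dx).notna() & ~pd.Series(dx).isin(DIAGNOSIS_CATEGORIES)
        if bad_dx.any():
            raise ValueError(f"unrecognised {pref}_diagnosis value: "
                             f"{dx[bad_dx.to_numpy()][0]!r}")
        bad_mg = pd.Series(mg).notna() & ~pd.Series(mg).isin(MANAGED_CATEGORIES)
        if bad_mg.any():
            raise ValueError(f"unrecognised {pref}_managed value: "
                             f"{mg[bad_mg.to_numpy()][0]!r}")
        mg_known = pd.Series(mg).notna().to_numpy()
        lv = np.full(n, "unknown", dtype=object)
        yes, no, unsure = dx == "yes", dx == "no", dx == "unsure"
        lv[yes & mg_known & (mg == "medically_managed")] = "low"
        lv[yes & cu_known & cu & (mg == "working_toward")] = "medium"
        lv[yes & cu_known & mg_known
           & ~(cu & (mg == "working_toward")) & (mg != "medically_managed")] = "high"
        lv[no & cu_known & cu] = "low"
        lv[no & cu_known & ~cu] = "high"
        lv[unsure & cu_known & cu] = "medium"
        levels[domain] = lv

    # smoking
    smoking = df["smoking"].astype(object)
    bad = smoking.notna() & ~smoking.isin(SMOKING_CATEGORIES)
    if bad.any():
        raise ValueError(f"unrecognised smoking value: {smoking[bad].iloc[0]!r}")
    lv = np.full(n, "unknown", dtype=object)
    lv[(smoking == "none").to_numpy()] = "low"
    lv[(smoking == "occasional").to_numpy()] = "medium"
    lv[(smoking == "weekly_or_more").to_numpy()] = "high"
    levels["smoking"] = lv

    # cognitive activity
    cog = df[COGNITIVE_COLUMNS].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any((cog < 0) | (cog > COGNITIVE_SCALE_MAX)):
        raise ValueError("cognitive frequency codes must lie in 0..5")
    cog_sum = cog.sum(axis=1)  # NaN if any item missing
    lv = np.full(n, "unknown", dtype=object)
    known = ~np.isnan(cog_sum)
    lv[known & (cog_sum >= COGNITIVE_SUFFICIENT)] = "low"
    lv[known & (cog_sum < COGNITIVE_SUFFICIENT)] = "high"
    levels["cognitive_activity"] = lv
    out["cognitive_score"] = cog_sum

    # physical activity
    met = (MET_WEIGHTS["light"] * num["light_min"]
           + MET_WEIGHTS["moderate"] * num["moderate_min"]
           + MET_WEIGHTS["vigorous"] * num["vigorous_min"])
    lv = np.full(n, "unknown", dtype=object)
    known = ~np.isnan(met)
    lv[known & (met >= MET_SUFFICIENT)] = "low"
    lv[known & (met < MET_SUFFICIENT)] = "high"
    levels["physical_activity"] = lv
    out["met_minutes"] = met

    # diet (MIND adherence)
    mind = df[MIND_COLUMNS].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    valid = np.isnan(mind) | np.isin(mind, (0.0, 0.5, 1.0))
    if not valid.all():
        raise ValueError("MIND components must be 0, 0.5 or 1")
    adherence = np.clip(mind.sum(axis=1), 0.0, MIND_N_COMPONENTS)
    lv = np.full(n, "unknown", dtype=object)
    known = ~np.isnan(adherence)
    lv[known & (adherence >= MIND_LOW)] = "low"
    lv[known & (adherence >= MIND_MEDIUM) & (adherence < MIND_LOW)] = "medium"
    lv[known & (adherence < MIND_MEDIUM)] = "high"
    levels["diet"] = lv
    out["mind_adherence"] = adherence

    weight_map = {"low": 0.0, "medium": 0.5, "high": 1.0, "unknown": np.nan}
    weights = np.zeros(n)
    n_unknown = np.zeros(n, dtype=int)
    for d in DOMAINS:
        out[f"risk_{d}"] = levels[d]
        w = np.array([weight_map[x] for x in levels[d]])
        n_unknown += np.isnan(w).astype(int)
        weights = weights + w
    out["n_unknown"] = n_unknown
    out["drp_total"] = weights  # NaN wherever any domain is unknown
    return out
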
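"""Analysis-panel assembly: wave timing, intervention-exposure coding and
sample filters.

The unit of analysis is a long-format panel with one row per participant ×
completed survey wave.  Key derived columns:

``months_in_study``
    Whole-month difference between the row's wave date and the
    participant's baseline date (0 at baseline).  The personalised risk
    report is released immediately after each completed survey, so time in
    study is time since first report exposure.
``log_time``
    ``log(months_in_study + 1)`` (natural log); the time metric entering
    the trajectory models.
``n_drp_exposures``
    Number of risk-report exposures accrued *before* the row's outcome was
    observed = count of the participant's completed waves strictly before
    this wave (baseline rows carry 0; a participant with baseline plus only
    the final annual wave has 1 exposure at that final row).
``pdmooc``
    1 from the first wave at/after completing at least module 1 of the
    online prevention course, else 0.  Pre-enrolled participants (course
    record predating the study) are 1 from baseline when retained.

The analysis-sample filters retain participants with a baseline inside the
recruitment window and at least one follow-up, and exclude (or, optionally,
retain flagged as exposed) those who engaged with the course before
joining.  Every excluded row lands in exactly one exclusion-reason bucket.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import (koderr_item_columns, mchlb_item_columns,
                          score_koderr, score_mchlb,
                          KODERR_SUBSCALES, MCHLB_DIMENSIONS)
from .scoring import score_dataframe

__all__ = [
    "month_diff",
    "derive_exposures",
    "apply_analysis_filters",
    "build_panel",
    "continuous_model_input",
    "ExclusionReport",
    "DEFAULT_BASELINE_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_WINDOW = ("2019-10-01", "2022-06-30")


def month_diff(start: pd.Series, end: pd.Series) -> pd.Series:
    """Whole-month difference between two date series (end - start)."""
    s, e = pd.to_datetime(start), pd.to_datetime(end)
    months = (e.dt.year - s.dt.year) * 12 + (e.dt.month - s.dt.month)
    return (months - (e.dt.day < s.dt.day).astype(int)).astype(int)


@dataclass
class ExclusionReport:
    """Bookkeeping for sample filters: row/participant counts by reason."""

    n_input_rows: int = 0
    n_retained_rows: int = 0
    excluded_rows: dict[str, int] = field(default_factory=dict)
    excluded_participants: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_rows": self.n_input_rows,
                "n_retained_rows": self.n_retained_rows,
                "excluded_rows": self.excluded_rows,
                "excluded_participants": self.excluded_participants,
            },
            sort_keys=True, indent=2,
        )


def derive_exposures(raw_waves: pd.DataFrame,
                     pdmooc_records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derive wave timing and exposure columns from completed survey rows.

    ``raw_waves`` needs ``participant_id`` and ``wave_date``; each row is a
    completed survey.  ``pdmooc_records`` (optional) maps
    ``participant_id`` → ``module1_date`` (course module-1 completion) and
    optional ``pre_study`` flag; alternatively the input may already carry
    ``pdmooc``/``pre_study_pdmooc`` columns.

    Follow-up rows whose participant has no baseline row cannot be timed
    and are dropped with a warning.
    """
    df = raw_waves.copy()
    df["wave_date"] = pd.to_datetime(df["wave_date"])
    df = df.sort_values(["participant_id", "wave_date"], kind="mergesort")
    df = df.reset_index(drop=True)

    grp = df.groupby("participant_id", sort=False)
    baseline_date = grp["wave_date"].transform("min")
    df["baseline_date"] = baseline_date
    df["months_in_study"] = month_diff(baseline_date, df["wave_date"])
    df["log_time"] = np.log(df["months_in_study"] + 1.0)
    df["n_drp_exposures"] = grp.cumcount()

    if "wave" not in df.columns:
        is_bl = df["months_in_study"] == 0
        df["wave"] = np.where(
            is_bl, "BL", df["wave_date"].dt.strftime("Oct-%y"))

    if pdmooc_records is not None:
        rec = pdmooc_records.set_index("participant_id")
        m1 = pd.to_datetime(
            df["participant_id"].map(rec["module1_date"]), errors="coerce")
        df["pdmooc"] = ((m1.notna()) & (df["wave_date"] >= m1)).astype(int)
        if "pre_study" in rec.columns:
            pre = df["participant_id"].map(rec["pre_study"]).fillna(False)
            df["pre_study_pdmooc"] = pre.astype(bool)
            df.loc[df["pre_study_pdmooc"], "pdmooc"] = 1
    elif "pdmooc" not in df.columns:
        df["pdmooc"] = 0
    if "pre_study_pdmooc" not in df.columns:
        df["pre_study_pdmooc"] = False
    return df


def apply_analysis_filters(panel: pd.DataFrame,
                           baseline_window: tuple[str, str] = DEFAULT_BASELINE_WINDOW,
                           require_followup: bool = True,
                           retain_pre_enrolled: bool = False,
                           ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the analysis-sample definition; returns (panel, report).

    Participants are dropped (all rows, one reason each, checked in order)
    when: they have follow-up data but no baseline row; their baseline
    falls outside ``baseline_window``; they engaged with the course before
    joining (unless ``retain_pre_enrolled``, which instead fixes
    ``pdmooc=1`` from baseline); or they have no follow-up survey.
    Idempotent: re-filtering a filtered panel changes nothing.
    """
    report = ExclusionReport(n_input_rows=len(panel))
    df = panel.copy()
    df["wave_date"] = pd.to_datetime(df["wave_date"])
    lo, hi = pd.Timestamp(baseline_window[0]), pd.Timestamp(baseline_window[1])

    per = df.groupby("participant_id").agg(
        baseline_date=("baseline_date", "min"),
        has_baseline=("months_in_study", lambda m: (m == 0).any()),
        n_waves=("wave_date", "size"),
        pre=("pre_study_pdmooc", "any"),
    )
    reason = pd.Series("", index=per.index, dtype=object)
    reason[~per["has_baseline"]] = "no_baseline"
    in_window = (per["baseline_date"] >= lo) & (per["baseline_date"] <= hi)
    reason[(reason == "") & ~in_window] = "baseline_outside_window"
    if not retain_pre_enrolled:
        reason[(reason == "") & per["pre"]] = "pre_study_pdmooc"
    if require_followup:
        reason[(reason == "") & (per["n_waves"] < 2)] = "no_followup"

    for r in reason[reason != ""].unique():
        ids = reason.index[reason == r]
        report.excluded_participants[r] = int(len(ids))
        report.excluded_rows[r] = int(df["participant_id"].isin(ids).sum())
        logger.info("excluding %d participants (%d rows): %s",
                    len(ids), report.excluded_rows[r], r)

    keep = df["participant_id"].map(reason) == ""
    out = df[keep].copy()
    if retain_pre_enrolled:
        out.loc[out["pre_study_pdmooc"], "pdmooc"] = 1
    report.n_retained_rows = int(len(out))
    assert report.n_retained_rows + sum(report.excluded_rows.values()) \
        == report.n_input_rows
    return out.reset_index(drop=True), report


def continuous_model_input(panel: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for continuous DRP-total models: any observation with an
    unknown-coded domain (undefined total) is excluded."""
    return panel[panel["drp_total"].notna()].reset_index(drop=True)


def build_panel(raw: pd.DataFrame,
                pdmooc_records: pd.DataFrame | None = None,
                score_instruments: bool = True) -> pd.DataFrame:
    """Score a raw long-format survey table and derive the analysis panel.

    Runs behaviour scoring, instrument scoring (when the item columns are
    present) and exposure/timing derivation in one pass.
    """
    scored = score_dataframe(raw)
    if score_instruments:
        if all(c in raw.columns for s in KODERR_SUBSCALES
               for c in koderr_item_columns(s)):
            scored = pd.concat([scored, score_koderr(raw)], axis=1)
        if all(c in raw.columns for d in MCHLB_DIMENSIONS
               for c in mchlb_item_columns(d)):
            scored = pd.concat([scored, score_mchlb(raw)], axis=1)
    return derive_exposures(scored, pdmooc_records=pdmooc_records)
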
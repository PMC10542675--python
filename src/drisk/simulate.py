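"""Seed-reproducible synthetic longitudinal cohorts with known ground truth.

The generator emulates a rolling-baseline public-health cohort aged 50+
(annual October follow-up surveys over up to three years) whose behaviour
responses, when scored by :mod:`drisk.scoring`, induce a DRP total that
follows the linear mixed model

    drp_total = β₀ + u_i + β_exp·exposures + β_time·log(months+1)
                + β_mooc·pdmooc + β_int·exposures·pdmooc + covariates + ε

with a random intercept per participant.  Generation is latent-continuous-
then-categorical: a latent total is drawn from the model, mapped onto the
0.5-step grid by mean-preserving stochastic rounding, decomposed into nine
domain risk levels, and finally rendered as raw survey responses that score
back to exactly those levels (scoring round-trip).

To keep the conditional mean of the observed total exactly equal to the
linear predictor despite the 0–9 bounds, person effects use a symmetric
truncated normal and the residual draw is truncated symmetrically to the
distance from the nearer bound; only conditional means below 0 (rare under
the default parameters) are floored.

Knowledge (misconception discernment) is generated with its own trajectory
and carries the mediation wiring: engagement with the online course (X)
shifts knowledge by the ``a`` path, and knowledge feeds back into the DRP
total through the ``b`` path, so the marginal course effect equals the
configured β_mooc while the (a, b, c′ = β_mooc − a·b) decomposition holds.
``simulate_mediation_panel`` additionally provides a direct path-equation
generator with exact standardized-path truth for estimator-recovery work.

Determinism: every participant draws from an independent substream derived
from ``(seed, participant_index)``, so enlarging the cohort never perturbs
earlier participants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scoring
from .instruments import (KODERR_SUBSCALES, MCHLB_DIMENSIONS,
                          koderr_item_columns, mchlb_item_columns)
from .scoring import DOMAINS, THREE_LEVEL_DOMAINS, TWO_LEVEL_DOMAINS

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "inject_missingness",
           "simulate_mediation_panel", "default_config_path"]


def default_config_path() -> Path:
    """Shipped default cohort configuration (paper-anchored descriptives)."""
    return Path(__file__).parent / "data" / "default_cohort.yaml"


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    Effects are on the raw DRP-total scale (points of risk score).  The
    course engagement coefficient ``beta_pdmooc`` is the *marginal* course
    effect; the direct path used internally is c′ = β_mooc − a·b so the
    mediation decomposition and the trajectory model agree.
    """

    n_participants: int = 3038
    seed: int = 0

    # --- schedule -----------------------------------------------------
    baseline_start: str = "2019-10-01"
    baseline_end: str = "2022-06-30"
    followup_years: tuple[int, ...] = (2020, 2021, 2022)
    eligibility_lead_months: int = 5
    baseline_decay_months: float = 5.0  # exp. decay of enrolment over window
    response_rates: dict = field(
        default_factory=lambda: {2020: 0.82, 2021: 0.70, 2022: 0.985})

    # --- interventions ------------------------------------------------
    pdmooc_rate: float = 0.588
    pre_study_pdmooc_rate: float = 0.0

    # --- demographics -------------------------------------------------
    age_mean: float = 63.7
    age_sd: float = 7.7
    age_min: float = 50.0
    age_max: float = 95.0
    female_prop: float = 0.716
    gender_probs: dict = field(default_factory=lambda: {
        "female": 0.716, "male": 0.282, "other": 0.002})
    education_probs: dict = field(default_factory=lambda: {
        "university": 0.553, "post_secondary": 0.279, "school_only": 0.130,
        "unknown": 0.038})
    marital_probs: dict = field(default_factory=lambda: {
        "married_defacto": 0.724, "not_married": 0.276})
    employment_probs: dict = field(default_factory=lambda: {
        "employed": 0.50, "retired": 0.45, "other": 0.05})
    irsad_probs: dict = field(default_factory=lambda: {
        str(d): p for d, p in zip(range(1, 11),
        [0.11, 0.11, 0.11, 0.0925, 0.0925, 0.0925, 0.0925, 0.10, 0.10, 0.10])})
    remoteness_probs: dict = field(default_factory=lambda: {
        "inner_regional": 0.734, "outer_regional": 0.255,
        "remote": 0.006, "very_remote": 0.005})

    # --- DRP-total trajectory (raw risk-score units) ------------------
    beta0: float = 2.17
    beta_exposure: float = -0.05
    beta_time: float = -0.10
    beta_pdmooc: float = -0.10
    beta_interaction: float = -0.04
    covariate_effects: dict = field(default_factory=lambda: {
        "age_c": 0.004, "male": 0.08, "school_only": 0.12, "irsad_decile": -0.015})
    sigma_u: float = 0.95
    sigma_e: float = 0.70
    trunc_sd: float = 2.5  # symmetric truncation of u and ε, in SDs

    # --- knowledge / motivation trajectories --------------------------
    generate_instruments: bool = True
    knowledge: dict = field(default_factory=lambda: {
        "mean": 7.0, "sd": 2.2, "stability": 0.6,
        "slope_exposure": 0.24, "residual_sd": 1.4})
    motivation: dict = field(default_factory=lambda: {
        "susceptibility": {"mean": 12.0, "sd": 2.6, "stability": 0.6,
                           "slope_exposure": -0.10, "pdmooc_gain": -0.10,
                           "residual_sd": 1.6},
        "severity": {"mean": 15.0, "sd": 3.0, "stability": 0.6,
                     "slope_exposure": -0.11, "pdmooc_gain": 0.0,
                     "residual_sd": 1.8},
        "benefits": {"mean": 15.0, "sd": 2.4, "stability": 0.6,
                     "slope_exposure": 0.07, "pdmooc_gain": 0.26,
                     "residual_sd": 1.5},
        "barriers": {"mean": 10.0, "sd": 2.6, "stability": 0.6,
                     "slope_exposure": 0.08, "pdmooc_gain": -0.49,
                     "residual_sd": 1.6},
        "cues_to_action": {"mean": 13.0, "sd": 2.5, "stability": 0.6,
                           "slope_exposure": 0.05, "pdmooc_gain": 0.0,
                           "residual_sd": 1.6},
        "self_efficacy": {"mean": 7.0, "sd": 1.5, "stability": 0.6,
                          "slope_exposure": 0.0, "pdmooc_gain": 0.23,
                          "residual_sd": 0.9},
        "general_health_motivation": {"mean": 15.0, "sd": 2.2, "stability": 0.6,
                                      "slope_exposure": -0.04,
                                      "pdmooc_gain": 0.18, "residual_sd": 1.4},
    })

    # --- mediation truth (standardized-path units) --------------------
    mediation_a: float = 0.41   # X -> knowledge, in knowledge-SD units
    mediation_b: float = -0.05  # knowledge -> DRP, Y-SD per knowledge-SD

    # --- categorical structure ----------------------------------------
    # escalation propensities per domain: (elevated weight, high-given-
    # elevated weight); anchored to printed baseline level proportions
    domain_weights: dict = field(default_factory=lambda: {
        "alcohol": (0.278, 0.30), "bmi": (0.389, 0.39),
        "hypertension": (0.052, 0.63), "cholesterol": (0.162, 0.80),
        "diabetes": (0.165, 0.92), "smoking": (0.026, 0.59),
        "cognitive_activity": (0.409, 1.0), "physical_activity": (0.089, 1.0),
        "diet": (0.422, 0.07)})

    # --- missingness ---------------------------------------------------
    apply_missingness: bool = True
    unknown_rates: dict = field(default_factory=lambda: {
        "alcohol": 0.068, "bmi": 0.044, "hypertension": 0.005,
        "cholesterol": 0.006, "diabetes": 0.008, "smoking": 0.002,
        "cognitive_activity": 0.011, "physical_activity": 0.030,
        "diet": 0.005})

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in ("gender_probs", "education_probs", "marital_probs",
                     "employment_probs", "irsad_probs", "remoteness_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name} has probabilities outside [0, 1]")
        if self.sigma_u <= 0 or self.sigma_e <= 0:
            raise ValueError("sigma_u and sigma_e must be > 0")
        if not 0 <= self.pdmooc_rate <= 1:
            raise ValueError("pdmooc_rate must lie in [0, 1]")
        for year, r in self.response_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"response rate for {year} outside [0, 1]: {r}")
        for d, r in self.unknown_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"unknown rate for {d} outside [0, 1]: {r}")
        years = sorted(self.followup_years)
        if list(self.followup_years) != years:
            raise ValueError("followup_years must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "followup_years" in raw:
            raw["followup_years"] = tuple(raw["followup_years"])
        if "response_rates" in raw:
            raw["response_rates"] = {int(k): v for k, v in
                                     raw["response_rates"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["followup_years"] = list(d["followup_years"])
        d["domain_weights"] = {k: list(v) for k, v in d["domain_weights"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SimTruth:
    """Generating truth recorded alongside a simulated cohort."""

    config: SimConfig
    random_intercepts: np.ndarray
    c_prime: float            # direct course→DRP path, raw Y units
    a_raw: float              # course→knowledge path, knowledge raw units
    b_raw: float              # knowledge→DRP path, Y units per knowledge unit
    latent_totals: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["followup_years"] = list(cfg["followup_years"])
        cfg["domain_weights"] = {k: list(v) for k, v in
                                 cfg["domain_weights"].items()}
        payload = {
            "config": cfg,
            "c_prime": self.c_prime,
            "a_raw": self.a_raw,
            "b_raw": self.b_raw,
            "random_intercepts": [round(float(x), 10)
                                  for x in self.random_intercepts],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def _trunc_normal(rng, sd, size, width):
    """Normal(0, sd²) truncated symmetrically at ±width·sd (mean exactly 0)."""
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > width * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > width * sd
    return out


def _stochastic_round_half(rng, x):
    """Round to the 0.5 grid preserving the conditional mean."""
    g = np.floor(np.asarray(x, dtype=float) / 0.5) * 0.5
    frac = (x - g) / 0.5
    return g + 0.5 * (rng.random(np.shape(x)) < frac)


def _categorical(rng, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _decompose_total(rng, total: float, weights: dict) -> dict[str, float]:
    """Split a grid total in [0, 9] into per-domain weights (0/0.5/1).

    Escalates domains one level at a time, sampling among the feasibility-
    preserving candidates with the configured propensities.  Two-level
    domains escalate low→high in a single 1.0-point step.
    """
    state = {d: 0.0 for d in DOMAINS}
    r = int(round(total * 2))  # remaining half-steps
    if not 0 <= r <= 18:
        raise ValueError(f"total out of range [0, 9]: {total}")
    while r > 0:
        half_avail = sum(int((1.0 - state[d]) * 2) for d in THREE_LEVEL_DOMAINS)
        full_avail = sum(1 for d in TWO_LEVEL_DOMAINS if state[d] == 0.0)
        cand, w = [], []
        for d in THREE_LEVEL_DOMAINS:
            if state[d] >= 1.0:
                continue
            # after taking one half-step: r-1 remaining, half_avail-1 left
            if (r - 1) > (half_avail - 1) + 2 * full_avail:
                continue
            w1, w2 = weights[d]
            cand.append(d)
            w.append(w1 if state[d] == 0.0 else w1 * w2)
        for d in TWO_LEVEL_DOMAINS:
            if state[d] != 0.0 or r < 2:
                continue
            r2, h2, f2 = r - 2, half_avail, full_avail - 1
            if r2 > h2 + 2 * f2 or (r2 % 2 == 1 and h2 < 1):
                continue
            cand.append(d)
            w.append(weights[d][0])
        if not cand:  # unreachable for totals on the grid, guarded anyway
            raise RuntimeError(f"cannot decompose total {total}")
        p = np.array(w, dtype=float)
        d = cand[rng.choice(len(cand), p=p / p.sum())]
        if d in TWO_LEVEL_DOMAINS:
            state[d] = 1.0
            r -= 2
        else:
            state[d] += 0.5
            r -= 1
    return state


# ---------------------------------------------------------------------------
# raw-response rendering (inverse of the scorers, by construction)
# ---------------------------------------------------------------------------

def _raw_alcohol(rng, level):
    if level == 0.0:
        if rng.random() < 0.3:
            return {"abstains": True, "drinks_per_week": 0.0,
                    "max_drinks_per_occasion": 0.0}
        return {"abstains": False,
                "drinks_per_week": round(float(rng.uniform(0, 14)), 1),
                "max_drinks_per_occasion": round(float(rng.uniform(0, 2)), 1)}
    if level == 0.5:
        return {"abstains": False,
                "drinks_per_week": round(float(rng.uniform(3, 14)), 1),
                "max_drinks_per_occasion": round(float(rng.uniform(2.5, 6)), 1)}
    return {"abstains": False,
            "drinks_per_week": round(float(rng.uniform(14.5, 40)), 1),
            "max_drinks_per_occasion": round(float(rng.uniform(1, 8)), 1)}


def _raw_bmi(rng, level, height):
    # 0.1 BMI margin at every cut point: weight is reported to 0.1 kg, which
    # can move recomputed BMI by at most ~0.026 at the minimum height
    if level == 0.0:
        bmi = rng.uniform(18.1, 24.9)
    elif level == 0.5:
        bmi = rng.uniform(16.0, 17.9) if rng.random() < 0.05 \
            else rng.uniform(25.1, 29.9)
    else:
        bmi = rng.uniform(30.1, 45.0)
    h = round(height, 2)
    return {"height_m": h, "weight_kg": round(float(bmi * h**2), 1)}


def _raw_cardio(rng, level, prefix, dx_given_low=0.3):
    if level == 0.0:
        if rng.random() < dx_given_low:
            return {f"{prefix}_diagnosis": "yes", f"{prefix}_checkups": True,
                    f"{prefix}_managed": "medically_managed"}
        return {f"{prefix}_diagnosis": "no", f"{prefix}_checkups": True,
                f"{prefix}_managed": "n/a"}
    if level == 0.5:
        if rng.random() < 0.5:
            return {f"{prefix}_diagnosis": "unsure", f"{prefix}_checkups": True,
                    f"{prefix}_managed": "n/a"}
        return {f"{prefix}_diagnosis": "yes", f"{prefix}_checkups": True,
                f"{prefix}_managed": "working_toward"}
    if rng.random() < 0.5:
        return {f"{prefix}_diagnosis": "yes", f"{prefix}_checkups": False,
                f"{prefix}_managed": "unmanaged"}
    return {f"{prefix}_diagnosis": "no", f"{prefix}_checkups": False,
            f"{prefix}_managed": "n/a"}


def _raw_smoking(rng, level):
    return {"smoking": {0.0: "none", 0.5: "occasional",
                        1.0: "weekly_or_more"}[level]}


def _raw_cognitive(rng, level):
    codes = rng.integers(3, 6, 11) if level == 0.0 else rng.integers(0, 3, 11)
    return {f"cog_{i + 1}": int(codes[i]) for i in range(11)}


def _raw_physical(rng, level):
    if level == 0.0:
        return {"light_min": round(float(rng.uniform(0, 300))),
                "moderate_min": round(float(rng.uniform(150, 500))),
                "vigorous_min": round(float(rng.uniform(0, 120)))}
    return {"light_min": round(float(rng.uniform(0, 60))),
            "moderate_min": round(float(rng.uniform(0, 100))),
            "vigorous_min": 0.0}


def _raw_mind(rng, level):
    if level == 0.0:
        target = rng.choice([12.0, 12.5, 13.0, 13.5, 14.0])
    elif level == 0.5:
        target = rng.choice(np.arange(7.5, 12.0, 0.5))
    else:
        target = rng.choice(np.arange(0.0, 7.5, 0.5))
    comps = np.ones(14)
    deficit = int(round((14.0 - target) * 2))  # in half-steps
    order = rng.permutation(14)
    k = 0
    while deficit > 0:
        i = order[k % 14]
        if comps[i] > 0:
            comps[i] -= 0.5
            deficit -= 1
        k += 1
    return {f"mind_{i + 1}": float(comps[i]) for i in range(14)}


def _render_domain_responses(rng, levels: dict[str, float], height: float) -> dict:
    row = {}
    row.update(_raw_alcohol(rng, levels["alcohol"]))
    row.update(_raw_bmi(rng, levels["bmi"], height))
    row.update(_raw_cardio(rng, levels["hypertension"], "htn", 0.35))
    row.update(_raw_cardio(rng, levels["cholesterol"], "chol", 0.30))
    row.update(_raw_cardio(rng, levels["diabetes"], "diab", 0.10))
    row.update(_raw_smoking(rng, levels["smoking"]))
    row.update(_raw_cognitive(rng, levels["cognitive_activity"]))
    row.update(_raw_physical(rng, levels["physical_activity"]))
    row.update(_raw_mind(rng, levels["diet"]))
    return row


def _instrument_items(rng, targets: dict[str, float]) -> dict:
    """Render item responses that sum/count back to the target scores."""
    row = {}
    for name, (n, _rng_) in KODERR_SUBSCALES.items():
        score = int(np.clip(round(targets[name]), 0, n))
        correct = rng.permutation(n) < score
        for j, col in enumerate(koderr_item_columns(name)):
            row[col] = 1 if correct[j] else 0
    for name, (n, (lo, hi), rng_range) in MCHLB_DIMENSIONS.items():
        score = int(np.clip(round(targets[name]), n * lo, n * hi))
        items = np.full(n, lo)
        surplus = score - n * lo
        order = rng.permutation(n)
        k = 0
        while surplus > 0:
            i = order[k % n]
            if items[i] < hi:
                items[i] += 1
                surplus -= 1
            k += 1
        for j, col in enumerate(mchlb_item_columns(name)):
            row[col] = int(items[j])
    return row


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _baseline_offset_months(rng, cfg: SimConfig) -> int:
    start = pd.Timestamp(cfg.baseline_start)
    end = pd.Timestamp(cfg.baseline_end)
    span = (end.year - start.year) * 12 + (end.month - start.month)
    m = np.arange(span + 1)
    w = np.exp(-m / cfg.baseline_decay_months)
    return int(rng.choice(m, p=w / w.sum()))


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None
                    ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate raw per-participant-per-wave survey tables plus truth.

    Returns ``(raw, truth)`` where ``raw`` follows the long-format schema
    consumed by :func:`drisk.cohort.build_panel` and ``truth`` records the
    generating coefficients and random intercepts.
    """
    cfg = config or SimConfig.from_yaml(default_config_path())
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    start = pd.Timestamp(cfg.baseline_start)

    kn = cfg.knowledge
    a_raw = cfg.mediation_a * kn["sd"]
    sd_y_nominal = float(np.hypot(cfg.sigma_u, cfg.sigma_e))
    b_raw = cfg.mediation_b * sd_y_nominal / kn["sd"]
    c_prime = cfg.beta_pdmooc - cfg.mediation_a * cfg.mediation_b * sd_y_nominal

    rows = []
    intercepts = np.empty(cfg.n_participants)
    for i in range(cfg.n_participants):
        rng = np.random.default_rng([seed, i])
        pid = f"P{i:05d}"

        # demographics
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd),
                            cfg.age_min, cfg.age_max))
        gender = _categorical(rng, cfg.gender_probs)
        education = _categorical(rng, cfg.education_probs)
        marital = _categorical(rng, cfg.marital_probs)
        employment = _categorical(rng, cfg.employment_probs)
        irsad = int(_categorical(rng, cfg.irsad_probs))
        remoteness = _categorical(rng, cfg.remoteness_probs)
        height = float(np.clip(rng.normal(1.68, 0.09), 1.40, 2.05))

        cov = (cfg.covariate_effects.get("age_c", 0.0) * (age - cfg.age_mean)
               + cfg.covariate_effects.get("male", 0.0) * (gender == "male")
               + cfg.covariate_effects.get("school_only", 0.0)
               * (education == "school_only")
               + cfg.covariate_effects.get("irsad_decile", 0.0) * (irsad - 5.5))

        # schedule
        offset = _baseline_offset_months(rng, cfg)
        bl_date = start + pd.DateOffset(months=offset)
        bl_date += pd.Timedelta(days=int(rng.integers(0, 28)))
        waves = [("BL", bl_date)]
        for year in cfg.followup_years:
            wave_date = pd.Timestamp(year=year, month=10, day=1)
            lead = (wave_date.year - bl_date.year) * 12 \
                + (wave_date.month - bl_date.month)
            if lead < cfg.eligibility_lead_months:
                continue
            if rng.random() < cfg.response_rates.get(year, 1.0):
                waves.append((f"Oct-{str(year)[2:]}", wave_date))

        # interventions
        pre_study = rng.random() < cfg.pre_study_pdmooc_rate
        engaged = pre_study or (rng.random() < cfg.pdmooc_rate)
        module1_date = bl_date + pd.Timedelta(days=30) if engaged else None
        if pre_study:
            module1_date = bl_date

        u = _trunc_normal(rng, cfg.sigma_u, 1, cfg.trunc_sd)[0]
        intercepts[i] = u

        m_bl = float(np.clip(rng.normal(kn["mean"], kn["sd"]), 0, 12))
        mot_bl = {k: float(np.clip(rng.normal(v["mean"], v["sd"]),
                                   *_mot_bounds(k)))
                  for k, v in cfg.motivation.items()}

        for wave, wave_date in waves:
            months = (wave_date.year - bl_date.year) * 12 \
                + (wave_date.month - bl_date.month) \
                - int(wave_date.day < bl_date.day)
            months = max(months, 0)
            exposures = 0 if wave == "BL" else \
                sum(1 for w, d in waves if d < wave_date)
            x = int(module1_date is not None and wave_date >= module1_date)

            # knowledge trajectory (mediator latent)
            if wave == "BL":
                m_latent = m_bl
            else:
                m_latent = (kn["mean"] + kn["stability"] * (m_bl - kn["mean"])
                            + kn["slope_exposure"] * exposures + a_raw * x
                            + rng.normal(0, kn["residual_sd"]))
            m_latent = float(np.clip(m_latent, 0, 12))

            # the knowledge feed-through (b path) would otherwise add
            # b·a to the course effect and b·slope to the exposure effect;
            # both are netted out so the configured betas stay the marginal
            # trajectory truth while the (a, b, c') decomposition holds
            eta = (cfg.beta0 + u + cov
                   + (cfg.beta_exposure - b_raw * kn["slope_exposure"])
                   * exposures
                   + cfg.beta_time * np.log(months + 1.0)
                   + c_prime * x
                   + cfg.beta_interaction * exposures * x
                   + b_raw * (m_latent - kn["mean"]))
            half_w = min(cfg.trunc_sd * cfg.sigma_e, eta, 9.0 - eta)
            if half_w <= 0:
                latent = float(np.clip(eta, 0.0, 9.0))
            else:
                latent = eta + _trunc_normal(
                    rng, cfg.sigma_e, 1,
                    half_w / cfg.sigma_e)[0]
            total = float(_stochastic_round_half(rng, np.array(latent)))
            total = float(np.clip(total, 0.0, 9.0))
            levels = _decompose_total(rng, total, cfg.domain_weights)

            row = {
                "participant_id": pid, "wave": wave,
                "wave_date": wave_date.strftime("%Y-%m-%d"),
                "age": round(age, 1), "gender": gender,
                "education": education, "marital": marital,
                "employment": employment, "irsad_decile": irsad,
                "remoteness": remoteness,
                "pdmooc": x, "pre_study_pdmooc": pre_study,
                "latent_drp": round(float(latent), 4),
                "target_drp_total": total,
            }
            row.update(_render_domain_responses(rng, levels, height))

            if cfg.generate_instruments:
                targets = {"misconception_discernment": m_latent}
                gen_bl = m_bl / 12 * 22  # general tracks misconception latent
                strat_bl = m_bl / 12 * 20
                if wave == "BL":
                    targets["general_knowledge"] = gen_bl
                    targets["strategy_knowledge"] = strat_bl
                else:
                    targets["general_knowledge"] = float(np.clip(
                        gen_bl + 0.3 * exposures + 0.8 * x
                        + rng.normal(0, 1.8), 0, 22))
                    targets["strategy_knowledge"] = float(np.clip(
                        strat_bl + 0.9 * exposures + 0.4 * x
                        + rng.normal(0, 1.8), 0, 20))
                for mname, mcfg in cfg.motivation.items():
                    if wave == "BL":
                        targets[mname] = mot_bl[mname]
                    else:
                        targets[mname] = (
                            mcfg["mean"]
                            + mcfg["stability"] * (mot_bl[mname] - mcfg["mean"])
                            + mcfg["slope_exposure"] * exposures
                            + mcfg["pdmooc_gain"] * x
                            + rng.normal(0, mcfg["residual_sd"]))
                row.update(_instrument_items(rng, targets))
            rows.append(row)

    raw = pd.DataFrame(rows)
    truth = SimTruth(config=cfg, random_intercepts=intercepts,
                     c_prime=c_prime, a_raw=a_raw, b_raw=b_raw)
    if cfg.apply_missingness:
        raw = inject_missingness(raw, cfg, seed)
    return raw, truth


def _mot_bounds(name):
    n, (lo, hi), rng_range = MCHLB_DIMENSIONS[name]
    return (n * lo, n * hi)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

_DOMAIN_INPUT_COLUMNS = {
    "alcohol": ["drinks_per_week", "max_drinks_per_occasion", "abstains"],
    "bmi": ["height_m", "weight_kg"],
    "hypertension": ["htn_diagnosis", "htn_checkups", "htn_managed"],
    "cholesterol": ["chol_diagnosis", "chol_checkups", "chol_managed"],
    "diabetes": ["diab_diagnosis", "diab_checkups", "diab_managed"],
    "smoking": ["smoking"],
    "cognitive_activity": [f"cog_{i}" for i in range(1, 12)],
    "physical_activity": ["light_min", "moderate_min", "vigorous_min"],
    "diet": [f"mind_{i}" for i in range(1, 15)],
}


def inject_missingness(tables: pd.DataFrame, config: SimConfig,
                       seed: int) -> pd.DataFrame:
    """MCAR-blank raw domain inputs at the configured per-domain rates.

    Rows selected for a domain get that domain's raw inputs blanked, which
    the scorer later codes as level 'unknown'.  Deterministic given
    ``(config, seed)``; a rate of 0 for every domain leaves the tables
    unchanged.
    """
    for d, r in config.unknown_rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"unknown rate for {d} outside [0, 1]: {r}")
    out = tables.copy()
    rng = np.random.default_rng([seed, 10_000_019])
    for d in DOMAINS:
        rate = config.unknown_rates.get(d, 0.0)
        if rate <= 0:
            continue
        mask = rng.random(len(out)) < rate
        cols = [c for c in _DOMAIN_INPUT_COLUMNS[d] if c in out.columns]
        for c in cols:
            if out[c].dtype == bool:
                out[c] = out[c].astype(object)
        out.loc[mask, cols] = np.nan
    return out


# ---------------------------------------------------------------------------
# direct path-equation generator for mediation estimator recovery
# ---------------------------------------------------------------------------

def simulate_mediation_panel(n: int, a: float, b: float, c_prime: float,
                             seed: int, x_rate: float = 0.588,
                             rho_m: float = 0.4, rho_y: float = 0.5
                             ) -> pd.DataFrame:
    """Five-variable mediation dataset with exact standardized-path truth.

    Variables are generated so each endogenous variable has unit variance
    and the population standardized paths equal (a, b, c′) for a z-scored
    binary exposure.  Columns: ``x, m_bl, m_fu, y_bl, y_fu``.
    """
    rng = np.random.default_rng([seed, 77_003])
    x = (rng.random(n) < x_rate).astype(float)
    xz = (x - x.mean()) / x.std()
    m_bl = rng.normal(0, 1, n)
    y_bl = rng.normal(0, 1, n)
    var_em = 1.0 - a**2 - rho_m**2
    if var_em <= 0:
        raise ValueError("a and rho_m imply non-positive mediator residual variance")
    m_fu = a * xz + rho_m * m_bl + rng.normal(0, np.sqrt(var_em), n)
    var_ey = 1.0 - (c_prime**2 + b**2 + rho_y**2 + 2 * c_prime * b * a)
    if var_ey <= 0:
        raise ValueError("paths imply non-positive outcome residual variance")
    y_fu = c_prime * xz + b * m_fu + rho_y * y_bl \
        + rng.normal(0, np.sqrt(var_ey), n)
    return pd.DataFrame({"x": x, "m_bl": m_bl, "m_fu": m_fu,
                         "y_bl": y_bl, "y_fu": y_fu})
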
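"""Longitudinal intervention-effect and risk-transition models.

Continuous outcomes (DRP total, instrument scores) are modelled with
random-intercept linear mixed models fitted by REML:

    y_iw = β₀ + u_i + β·exposures + β·log(months+1) [+ pdmooc
           + exposures×pdmooc + demographic covariates] + ε_iw

Effect sizes are reported as standardized coefficients b_s = b·SD(x)/SD(y)
(binary predictors: b/SD(y)), with 95% CIs.  Estimated marginal means are
evaluated on a reference grid with covariates at their estimation-sample
means; all-pairwise contrasts use Tukey studentized-range adjustment.
Fixed-/random-effect variance shares are summarised by the Nakagawa
marginal and conditional R².  Mixed-model inference uses the normal
approximation for fixed effects (labelled in output).

Categorical risk-level change from baseline to the final wave is modelled
per domain with multinomial logistic regression (reference level: low),
adjusted for covariates; results are odds ratios with 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.stats import studentized_range

from .scoring import DOMAINS

__all__ = [
    "ModelResult",
    "TransitionResult",
    "fit_trajectory",
    "standardize_coefficients",
    "marginal_means",
    "tukey_contrasts",
    "fit_transitions",
    "marginal_r2",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "C(gender)", "C(education)", "C(marital)",
                      "irsad_decile")


@dataclass
class ModelResult:
    """Tidy container for a fitted random-intercept mixed model."""

    outcome: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame           # raw scale
    standardized: pd.DataFrame       # b_s with CI per term
    var_random_intercept: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    inference: str = "normal approximation (z)"
    data: pd.DataFrame | None = field(default=None, repr=False)
    fitted: object | None = field(default=None, repr=False)

    def tidy(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "std_error": self.bse.values,
            "p_value": self.pvalues.values,
            "ci_low": self.conf_int[0].values,
            "ci_high": self.conf_int[1].values,
        })
        return out.merge(
            self.standardized.rename_axis("term").reset_index(), on="term",
            how="left")


def _build_formula(outcome, exposure_term, time_term, include_pdmooc,
                   interaction, covariates):
    terms = []
    if exposure_term:
        terms.append("n_drp_exposures")
    if time_term:
        terms.append("log_time")
    if include_pdmooc:
        terms.append("pdmooc")
    if interaction:
        if not (exposure_term and include_pdmooc):
            raise ValueError("interaction requires exposure and pdmooc terms")
        terms.append("n_drp_exposures:pdmooc")
    terms.extend(covariates or [])
    if not terms:
        terms = ["1"]
    return f"{outcome} ~ " + " + ".join(terms)


def fit_trajectory(panel: pd.DataFrame, outcome: str = "drp_total",
                   exposure_term: bool = True, time_term: bool = True,
                   include_pdmooc: bool = True, interaction: bool = True,
                   covariates: tuple[str, ...] | None = None) -> ModelResult:
    """Fit the REML random-intercept trajectory model for one outcome.

    Rows with a missing outcome (e.g. undefined DRP total from an
    unknown-coded domain) are excluded.  Raises on degenerate input
    (single wave overall, < 2 participants, collinear design).
    """
    formula = _build_formula(outcome, exposure_term, time_term,
                             include_pdmooc, interaction, covariates)
    cols = {outcome, "participant_id", "n_drp_exposures", "log_time", "pdmooc"}
    use = panel.dropna(subset=[c for c in cols if c in panel.columns]).copy()
    if use["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants to fit a mixed model")
    if use.groupby("participant_id").size().max() < 2:
        raise ValueError(
            "no participant has repeated observations; a random-intercept "
            "model is not identified on single-wave data")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, use, groups=use["participant_id"])
        _check_rank(model)
        fitted = None
        # gradient-based first; fall back to derivative-free when the
        # group variance collapses to the boundary
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                fitted = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fitted is None:
            raise np.linalg.LinAlgError("mixed-model fit failed")

    fe_names = model.exog_names
    params = fitted.fe_params.copy()
    bse = fitted.bse_fe.copy()
    pvalues = fitted.pvalues[fe_names].copy()
    ci = fitted.conf_int().loc[fe_names]
    ci.columns = [0, 1]

    var_u = float(np.asarray(fitted.cov_re)[0, 0])
    var_e = float(fitted.scale)
    r2m, r2c = _nakagawa_r2(model, fitted)

    std = standardize_coefficients(fitted, use, outcome, model=model)
    return ModelResult(
        outcome=outcome, formula=formula,
        params=params, bse=bse, pvalues=pvalues, conf_int=ci,
        standardized=std,
        var_random_intercept=var_u, var_residual=var_e,
        r2_marginal=r2m, r2_conditional=r2c,
        n_obs=int(model.exog.shape[0]),
        n_groups=int(use["participant_id"].nunique()),
        data=use, fitted=fitted)


def _check_rank(model):
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, r = np.linalg.qr(X)
        dep = [model.exog_names[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {dep}")


def standardize_coefficients(fitted, data: pd.DataFrame, outcome: str,
                             model=None) -> pd.DataFrame:
    """Standardized coefficients b_s = b·SD(x)/SD(y) with 95% CIs.

    Binary (two-valued 0/1) design columns are scaled by 1/SD(y) only; SDs
    come from the model's estimation sample.  Raises for a zero-variance
    predictor.
    """
    model = model or fitted.model
    X = np.asarray(model.exog)
    names = list(model.exog_names)
    sd_y = float(np.asarray(model.endog).std(ddof=1))
    params = fitted.fe_params if hasattr(fitted, "fe_params") else fitted.params
    bse = fitted.bse_fe if hasattr(fitted, "bse_fe") else fitted.bse

    rows = {}
    z = stats.norm.ppf(0.975)
    for j, name in enumerate(names):
        if name in ("Intercept", "const"):
            continue
        col = X[:, j]
        uniq = np.unique(col)
        if uniq.size < 2:
            raise ValueError(f"predictor {name!r} has zero variance")
        if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
            scale = 1.0 / sd_y
        else:
            scale = float(col.std(ddof=1)) / sd_y
        b = float(params[name]) * scale
        se = float(bse[name]) * scale
        rows[name] = {"b_s": b, "b_s_low": b - z * se, "b_s_high": b + z * se}
    return pd.DataFrame.from_dict(rows, orient="index")


def _nakagawa_r2(model, fitted):
    """Nakagawa variance decomposition for a random-intercept LMM."""
    fixed = np.asarray(model.exog) @ np.asarray(fitted.fe_params)
    var_f = float(np.var(fixed))
    var_u = float(np.asarray(fitted.cov_re)[0, 0])
    var_e = float(fitted.scale)
    denom = var_f + var_u + var_e
    return var_f / denom, (var_f + var_u) / denom


def marginal_r2(result: ModelResult) -> tuple[float, float]:
    """(marginal R², conditional R²) of a fitted trajectory model."""
    return result.r2_marginal, result.r2_conditional


# ---------------------------------------------------------------------------
# estimated marginal means + Tukey contrasts
# ---------------------------------------------------------------------------

def _design_rows(result: ModelResult, grid: pd.DataFrame) -> np.ndarray:
    """Design rows for the grid, non-grid covariates at sample means."""
    data = result.data
    fixed_part = result.formula.split("~", 1)[1]
    for col in grid.columns:
        if col not in data.columns and col not in fixed_part:
            raise ValueError(f"grid term {col!r} not in the fitted model")
    from patsy import dmatrix
    frames = []
    for _, g in grid.iterrows():
        d = data.copy()
        for col, val in g.items():
            d[col] = val
        M = np.asarray(dmatrix(fixed_part, d, return_type="matrix"))
        frames.append(M.mean(axis=0))
    return np.vstack(frames)


def marginal_means(result: ModelResult, grid: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Estimated marginal means over a reference grid.

    ``grid`` holds one row per condition (e.g. exposure counts, pdmooc
    strata); remaining model covariates are averaged over the estimation
    sample.  Returns EMMs with standard errors and CIs.
    """
    L = _design_rows(result, grid)
    beta = np.asarray(result.fitted.fe_params)
    V = np.asarray(result.fitted.cov_params())[:len(beta), :len(beta)]
    est = L @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, V, L))
    z = stats.norm.ppf(1 - alpha / 2)
    out = grid.copy().reset_index(drop=True)
    out["emm"] = est
    out["se"] = se
    out["ci_low"] = est - z * se
    out["ci_high"] = est + z * se
    return out


def tukey_contrasts(result: ModelResult, grid: pd.DataFrame,
                    labels: list[str] | None = None) -> pd.DataFrame:
    """All pairwise differences between grid EMMs, Tukey-adjusted.

    p-values use the studentized-range distribution with the family size
    equal to the number of grid points; adjusted p ≥ unadjusted p always.
    """
    L = _design_rows(result, grid)
    beta = np.asarray(result.fitted.fe_params)
    V = np.asarray(result.fitted.cov_params())[:len(beta), :len(beta)]
    est = L @ beta
    k = len(est)
    if labels is None:
        labels = [" & ".join(f"{c}={v}" for c, v in row.items())
                  for _, row in grid.iterrows()]
    df_resid = max(result.n_obs - len(beta), 1)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = L[i] - L[j]
            diff = est[i] - est[j]
            se = float(np.sqrt(c @ V @ c))
            q = abs(diff) / se * np.sqrt(2.0)
            p_adj = float(studentized_range.sf(q, k, df_resid))
            p_unadj = 2 * float(stats.t.sf(abs(diff) / se, df_resid))
            rows.append({"contrast": f"{labels[i]} - {labels[j]}",
                         "estimate": diff, "se": se,
                         "p_unadjusted": p_unadj,
                         "p_tukey": min(max(p_adj, p_unadj), 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multinomial risk-level transitions
# ---------------------------------------------------------------------------

@dataclass
class TransitionResult:
    """Per-domain multinomial transition model (final level vs baseline)."""

    domain: str
    odds_ratios: pd.DataFrame   # term × outcome-level OR with CIs
    n_obs: int
    categories: list[str]
    fitted: object | None = field(default=None, repr=False)

    def predicted_probabilities(self) -> np.ndarray:
        return self.fitted.predict()


def fit_transitions(baseline_levels: pd.Series, final_levels: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    domain: str = "", collapse_binary: bool = False
                    ) -> TransitionResult:
    """Multinomial logistic model of final risk level (reference: low).

    Predictors: baseline level (categorical) plus optional covariates.
    ``collapse_binary`` merges medium+high into 'elevated' on both axes,
    reducing to ordinary logistic regression.  Unknown levels are dropped.
    """
    df = pd.DataFrame({"baseline": baseline_levels.astype(str).values,
                       "final": final_levels.astype(str).values})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    df = df[(df["baseline"] != "unknown") & (df["final"] != "unknown")]
    df = df.dropna().reset_index(drop=True)
    if collapse_binary:
        for c in ("baseline", "final"):
            df[c] = np.where(df[c] == "low", "low", "elevated")
    order = [lv for lv in ("low", "medium", "high", "elevated")
             if lv in set(df["baseline"]) | set(df["final"])]

    y = pd.Categorical(df["final"], categories=order)
    X = pd.get_dummies(
        pd.Categorical(df["baseline"],
                       categories=[lv for lv in order
                                   if lv in set(df["baseline"])]),
        drop_first=True, prefix="baseline", dtype=float)
    if covariates is not None:
        cov_cols = [c for c in df.columns if c not in ("baseline", "final")]
        X = pd.concat([X, df[cov_cols].astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")

    empty = [lv for lv in y.categories if (np.asarray(y) == lv).sum() == 0]
    if empty:
        if X.shape[1] > 1:
            raise ValueError(
                f"final-level category {empty} is empty; consider collapsing "
                f"categories (collapse_binary=True)")
        y = pd.Categorical(df["final"],
                           categories=[lv for lv in order if lv not in empty])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(np.asarray(y.codes), X)
        try:
            fitted = model.fit(disp=0, maxiter=200)
            if np.isnan(np.asarray(fitted.params)).any():
                raise np.linalg.LinAlgError("NaN coefficients")
        except np.linalg.LinAlgError:
            # (quasi-)separated sparse cells: lightly penalised fit keeps
            # the coefficients finite; SEs may be undefined there
            fitted = model.fit_regularized(method="l1", alpha=1e-3, disp=0,
                                           maxiter=500)

    out_levels = list(y.categories)[1:]  # reference = first (low)
    rows = []
    params = np.asarray(fitted.params)          # k_params × k_eq
    bse = np.asarray(fitted.bse)
    pvals = np.asarray(fitted.pvalues)
    z = stats.norm.ppf(0.975)
    def _exp(v):  # avoid overflow for unbounded limits in sparse cells
        return float(np.exp(np.clip(v, -700, 700)))
    for k, lv in enumerate(out_levels):
        for j, term in enumerate(X.columns):
            b, se = params[j, k], bse[j, k]
            rows.append({"outcome_level": lv, "term": term,
                         "odds_ratio": _exp(b),
                         "or_low": _exp(b - z * se),
                         "or_high": _exp(b + z * se),
                         "p_value": float(pvals[j, k])})
    return TransitionResult(domain=domain, odds_ratios=pd.DataFrame(rows),
                            n_obs=len(df), categories=list(y.categories),
                            fitted=fitted)


def fit_all_transitions(panel: pd.DataFrame,
                        baseline_wave: str = "BL",
                        final_wave: str | None = None,
                        covariates: tuple[str, ...] = (),
                        use_last_available: bool = False) -> dict[str, TransitionResult]:
    """Baseline→final transition models for all nine domains.

    Default compares baseline with the latest wave label present (the
    final annual survey); ``use_last_available`` instead pairs each
    participant's own last wave.
    """
    bl = panel[panel["wave"] == baseline_wave].set_index("participant_id")
    if use_last_available:
        fu = (panel[panel["wave"] != baseline_wave]
              .sort_values("wave_date").groupby("participant_id").last())
    else:
        if final_wave is None:
            fu_rows = panel[panel["wave"] != baseline_wave]
            final_wave = fu_rows.loc[fu_rows["wave_date"].idxmax(), "wave"]
        fu = panel[panel["wave"] == final_wave].set_index("participant_id")
    common = bl.index.intersection(fu.index)
    results = {}
    for d in DOMAINS:
        cov = None
        if covariates:
            cov = bl.loc[common, list(covariates)].reset_index(drop=True)
        blv = bl.loc[common, f"risk_{d}"]
        fuv = fu.loc[common, f"risk_{d}"]
        try:
            results[d] = fit_transitions(blv, fuv, covariates=cov, domain=d)
        except (np.linalg.LinAlgError, ValueError):
            # sparse level (e.g. few medium smokers): collapse to binary
            results[d] = fit_transitions(blv, fuv, covariates=cov, domain=d,
                                         collapse_binary=True)
    return results
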
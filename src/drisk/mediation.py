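"""Baseline-adjusted three-variable mediation with bootstrap inference.

The path model regresses, on z-scored analysis-sample variables,

    M_fu ~ X + M_bl            (a path: exposure → mediator)
    Y_fu ~ X + M_fu + Y_bl     (b path and direct effect c′)

so all effects are in outcome/mediator SD units.  The indirect effect is
the product of coefficients a·b; the total effect is direct + indirect
(c = c′ + a·b, the path-model decomposition); ``c_marginal`` additionally
reports the exposure coefficient from the separate regression
Y_fu ~ X + Y_bl.  The proportion mediated is a·b/(a·b + c′) expressed in
percent, flagged inconsistent when the direct and indirect effects have
opposing signs.

Inference is by nonparametric case bootstrap (participants resampled with
replacement; percentile CIs; SE = SD of the bootstrap distribution).
Missing data are handled either by complete-case analysis or by EM
estimation of the multivariate-normal mean/covariance, from which path
coefficients are derived (equal to the complete-case coefficients when
nothing is missing).

Global fit is summarised by a likelihood-ratio χ² against the saturated
model, with CFI (vs the independence baseline) and RMSEA including a 90%
CI from noncentral-χ² inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MediationSpec",
    "MediationResult",
    "fit_mediation",
    "bootstrap",
    "fit_indices",
    "em_normal_estimates",
]

logger = logging.getLogger(__name__)

_VAR_ORDER = ("x", "m_bl", "y_bl", "m_fu", "y_fu")


@dataclass
class MediationSpec:
    """Column mapping and options for one mediation model."""

    x: str
    m_bl: str
    m_fu: str
    y_bl: str
    y_fu: str
    n_boot: int = 5000
    seed: int = 0
    missing: str = "complete_case"      # or "em_normal"
    include_m_bl_in_y_model: bool = False

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.missing not in ("complete_case", "em_normal"):
            raise ValueError(f"unknown missing policy: {self.missing!r}")
        fu = {self.m_fu, self.y_fu}
        if fu & {self.m_bl, self.y_bl}:
            raise ValueError("follow-up variables must differ from baselines")

    def columns(self) -> list[str]:
        return [self.x, self.m_bl, self.y_bl, self.m_fu, self.y_fu]


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    c: float                    # total = a·b + c′ (path decomposition)
    c_marginal: float           # exposure coefficient from Y_fu ~ X + Y_bl
    indirect: float
    proportion_mediated: float  # percent
    inconsistent_mediation: bool
    n_used: int
    boot: dict = field(default_factory=dict)   # per-quantity SE and CI
    cfi: float = float("nan")
    rmsea: float = float("nan")
    rmsea_ci: tuple[float, float] = (float("nan"), float("nan"))
    chi2: float = float("nan")
    df: int = 0
    n_boot_failures: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("a", "b", "c_prime", "c", "indirect"):
            row = {"quantity": name, "estimate": getattr(self, name)}
            if name in self.boot:
                row.update(self.boot[name])
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# path estimation from a covariance matrix
# ---------------------------------------------------------------------------

def _regress_from_cov(S: np.ndarray, yi: int, xi: list[int]) -> np.ndarray:
    return np.linalg.solve(S[np.ix_(xi, xi)], S[np.ix_(xi, [yi])]).ravel()


def _paths_from_cov(S: np.ndarray, include_m_bl_in_y: bool) -> dict:
    """a/b/c′ and auxiliary paths from the 5×5 covariance of
    (x, m_bl, y_bl, m_fu, y_fu)."""
    iX, iMb, iYb, iMf, iYf = range(5)
    a_coefs = _regress_from_cov(S, iMf, [iX, iMb])
    y_pred = [iX, iMf, iYb] + ([iMb] if include_m_bl_in_y else [])
    b_coefs = _regress_from_cov(S, iYf, y_pred)
    c_coefs = _regress_from_cov(S, iYf, [iX, iYb])
    return {"a": float(a_coefs[0]), "rho_m": float(a_coefs[1]),
            "c_prime": float(b_coefs[0]), "b": float(b_coefs[1]),
            "rho_y": float(b_coefs[2]),
            "c_marginal": float(c_coefs[0])}


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {c!r} has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def _point_estimates(data: pd.DataFrame, spec: MediationSpec) -> tuple[dict, int]:
    cols = spec.columns()
    sub = data[cols].apply(pd.to_numeric)
    if spec.missing == "complete_case":
        sub = sub.dropna()
        n = len(sub)
        if n < 5:
            raise ValueError(f"too few complete cases: {n}")
        z = _zscore(sub)
        S = np.cov(z.to_numpy().T, ddof=1)
        paths = _paths_from_cov(S, spec.include_m_bl_in_y_model)
        paths["S"] = S
        paths["arr"] = sub.to_numpy(dtype=float)
        return paths, n
    else:
        n = int(sub.notna().any(axis=1).sum())
        mu, S_full, _ = em_normal_estimates(sub)
        d = np.sqrt(np.diag(S_full))
        if np.any(d == 0):
            raise ValueError("zero-variance variable under EM")
        S = S_full / np.outer(d, d)   # correlation: paths on z-scale
    paths = _paths_from_cov(S, spec.include_m_bl_in_y_model)
    paths["S"] = S
    return paths, n


def fit_mediation(panel: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Fit the mediation model with bootstrap inference and fit indices.

    ``panel`` is wide (one row per participant) with the five columns named
    by ``spec``.  Raises for zero-variance exposure; flags (rather than
    silently reports) the proportion mediated under inconsistent mediation.
    """
    paths, n = _point_estimates(panel, spec)
    indirect = paths["a"] * paths["b"]
    total = indirect + paths["c_prime"]
    inconsistent = (np.sign(indirect) != 0 and np.sign(paths["c_prime"]) != 0
                    and np.sign(indirect) != np.sign(paths["c_prime"])
                    and abs(indirect) > abs(total))
    if inconsistent:
        logger.warning("inconsistent mediation: indirect and direct effects "
                       "oppose; proportion mediated is not interpretable")
    prop = 100.0 * indirect / total if total != 0 else float("nan")

    if spec.missing == "complete_case":
        boot = _bootstrap_paths_complete(paths.pop("arr"), spec)
    else:
        def stat(df):
            p, _ = _point_estimates(df, spec)
            ab = p["a"] * p["b"]
            return {"a": p["a"], "b": p["b"], "c_prime": p["c_prime"],
                    "c": ab + p["c_prime"], "indirect": ab}

        boot = bootstrap(panel, spec, stat)

    try:
        chi2, dfm, chi2_b, dfb = _model_chi2(paths["S"], n,
                                             spec.include_m_bl_in_y_model)
        cfi, rmsea, rmsea_ci = fit_indices_from_chi2(chi2, dfm, chi2_b, dfb, n)
    except np.linalg.LinAlgError:   # degenerate (e.g. zero-residual) data
        chi2, dfm = float("nan"), 0
        cfi, rmsea, rmsea_ci = float("nan"), float("nan"), (float("nan"),) * 2

    return MediationResult(
        a=paths["a"], b=paths["b"], c_prime=paths["c_prime"],
        c=total, c_marginal=paths["c_marginal"],
        indirect=indirect, proportion_mediated=prop,
        inconsistent_mediation=bool(inconsistent), n_used=n,
        boot=boot["stats"], n_boot_failures=boot["n_failures"],
        cfi=cfi, rmsea=rmsea, rmsea_ci=rmsea_ci, chi2=chi2, df=dfm)


def _bootstrap_paths_complete(arr: np.ndarray, spec: MediationSpec) -> dict:
    """Vectorised case bootstrap of the path coefficients (complete-case
    data as a numeric matrix); same resampling stream and summaries as
    :func:`bootstrap`."""
    rng = np.random.default_rng([spec.seed, 555_001])
    n = arr.shape[0]
    draws = {k: [] for k in ("a", "b", "c_prime", "c", "indirect")}
    n_failures = 0
    done = 0
    while done < spec.n_boot:
        idx = rng.integers(0, n, n)
        sample = arr[idx]
        sd = sample.std(axis=0, ddof=1)
        if np.any(sd == 0) or not np.all(np.isfinite(sd)):
            n_failures += 1
            if n_failures > 10 * spec.n_boot:
                raise RuntimeError("bootstrap failure rate too high")
            continue
        S = np.corrcoef(sample.T)
        try:
            p = _paths_from_cov(S, spec.include_m_bl_in_y_model)
        except np.linalg.LinAlgError:
            n_failures += 1
            continue
        ab = p["a"] * p["b"]
        for k, v in (("a", p["a"]), ("b", p["b"]), ("c_prime", p["c_prime"]),
                     ("c", ab + p["c_prime"]), ("indirect", ab)):
            draws[k].append(v)
        done += 1
    if n_failures:
        logger.info("bootstrap: %d resamples redrawn", n_failures)
    stats_out = {}
    for k, vals in draws.items():
        a = np.asarray(vals)
        se = float(a.std(ddof=1)) if len(a) > 1 else float("nan")
        lo, hi = (np.percentile(a, [2.5, 97.5]) if len(a) > 1
                  else (float("nan"), float("nan")))
        stats_out[k] = {"se": se, "ci_low": float(lo), "ci_high": float(hi),
                        "se_defined": len(a) > 1}
    return {"stats": stats_out, "n_failures": n_failures,
            "draws": {k: np.asarray(v) for k, v in draws.items()}}


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap(panel: pd.DataFrame, spec: MediationSpec, statistic,
              n_boot: int | None = None, seed: int | None = None) -> dict:
    """Nonparametric case bootstrap over participants (rows).

    ``statistic(df)`` returns a scalar or a dict of scalars.  Failing
    resamples are redrawn (count logged and reported).  Deterministic
    given the spec's seed.  With a single replicate the SE is undefined
    and flagged NaN.
    """
    n_boot = n_boot or spec.n_boot
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng([seed, 555_001])
    n = len(panel)
    draws: dict[str, list] = {}
    n_failures = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, n)
        try:
            val = statistic(panel.iloc[idx].reset_index(drop=True))
        except Exception:
            n_failures += 1
            if n_failures > 10 * n_boot:
                raise RuntimeError("bootstrap failure rate too high")
            continue
        if not isinstance(val, dict):
            val = {"stat": val}
        for k, v in val.items():
            draws.setdefault(k, []).append(float(v))
        done += 1
    if n_failures:
        logger.info("bootstrap: %d resamples redrawn", n_failures)
    stats_out = {}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        lo, hi = (np.percentile(arr, [2.5, 97.5]) if len(arr) > 1
                  else (float("nan"), float("nan")))
        stats_out[k] = {"se": se, "ci_low": float(lo), "ci_high": float(hi),
                        "se_defined": len(arr) > 1}
    return {"stats": stats_out, "n_failures": n_failures,
            "draws": {k: np.asarray(v) for k, v in draws.items()}}


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def _implied_sigma(S: np.ndarray, include_m_bl_in_y: bool) -> tuple[np.ndarray, int]:
    """Model-implied covariance for the recursive path model, plus df.

    Exogenous block (x, m_bl, y_bl) is saturated; structural equations
    give M_fu and Y_fu.  Omitted paths (y_bl→m_fu; m_bl→y_fu unless
    enabled; cov of the two residuals) are the model's constraints.
    """
    iX, iMb, iYb, iMf, iYf = range(5)
    p = 5
    paths = _paths_from_cov(S, include_m_bl_in_y)
    B = np.zeros((p, p))
    B[iMf, iX] = paths["a"]
    B[iMf, iMb] = paths["rho_m"]
    B[iYf, iX] = paths["c_prime"]
    B[iYf, iMf] = paths["b"]
    B[iYf, iYb] = paths["rho_y"]
    n_free = 6 + 3 + 4  # exogenous (co)variances + eqn params + residual vars
    if include_m_bl_in_y:
        B[iYf, iMb] = paths.get("b_mbl", 0.0)
        n_free += 1
    Psi = np.zeros((p, p))
    exo = [iX, iMb, iYb]
    Psi[np.ix_(exo, exo)] = S[np.ix_(exo, exo)]
    # residual variances from the fitted equations
    for yi, xi in ((iMf, [iX, iMb]),
                   (iYf, [iX, iMf, iYb] + ([iMb] if include_m_bl_in_y else []))):
        beta = _regress_from_cov(S, yi, xi)
        Psi[yi, yi] = S[yi, yi] - beta @ S[np.ix_(xi, [yi])].ravel()
    I = np.eye(p)
    inv = np.linalg.inv(I - B)
    sigma = inv @ Psi @ inv.T
    df = p * (p + 1) // 2 - n_free
    return sigma, df


def _model_chi2(S: np.ndarray, n: int, include_m_bl_in_y: bool):
    p = S.shape[0]
    sigma, dfm = _implied_sigma(S, include_m_bl_in_y)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    fmin = logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p
    chi2 = max(n * fmin, 0.0)
    # independence baseline: diagonal covariance
    diag = np.diag(np.diag(S))
    _, logdet_d = np.linalg.slogdet(diag)
    fb = logdet_d + np.trace(S @ np.linalg.inv(diag)) - logdet_s - p
    chi2_b = max(n * fb, 0.0)
    dfb = p * (p - 1) // 2
    return float(chi2), dfm, float(chi2_b), dfb


def fit_indices(loglik_model: float, loglik_saturated: float,
                loglik_baseline: float, df_model: int, df_baseline: int,
                n: int) -> tuple[float, float, tuple[float, float]]:
    """CFI and RMSEA (with 90% CI) from model/saturated/baseline logliks.

    χ²_m = 2(llsat − llm); CFI = 1 − max(χ²_m−df_m, 0)/max(χ²_b−df_b,
    χ²_m−df_m, 0); RMSEA = √(max(χ²_m−df_m,0)/(df_m·n)), CI by inverting
    the noncentral-χ² distribution.  df_model = 0 reports RMSEA 0
    (saturated model).
    """
    chi2_m = 2.0 * (loglik_saturated - loglik_model)
    chi2_b = 2.0 * (loglik_saturated - loglik_baseline)
    return fit_indices_from_chi2(chi2_m, df_model, chi2_b, df_baseline, n)


def fit_indices_from_chi2(chi2_m: float, df_m: int, chi2_b: float,
                          df_b: int, n: int
                          ) -> tuple[float, float, tuple[float, float]]:
    d_m = max(chi2_m - df_m, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    denom = max(d_b, d_m)
    cfi = 1.0 if denom == 0 else 1.0 - d_m / denom
    if df_m == 0:
        return cfi, 0.0, (0.0, 0.0)
    rmsea = float(np.sqrt(d_m / (df_m * n)))
    ci = _rmsea_ci(chi2_m, df_m, n)
    return float(cfi), rmsea, ci


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90
              ) -> tuple[float, float]:
    """90% RMSEA CI via noncentral-χ² inversion (lower tail prob 0.95 for
    the lower bound, 0.05 for the upper)."""
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2

    def ncp_for(prob):
        # find λ with ncx2.cdf(chi2, df, λ) = prob
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob
        if f(1e-10) < 0:     # even λ≈0 puts chi2 below the target quantile
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                return hi
        return optimize.brentq(f, 1e-10, hi, xtol=1e-8)

    lam_lo = ncp_for(lo_p)
    lam_hi = ncp_for(hi_p)
    return (float(np.sqrt(lam_lo / (df * n))), float(np.sqrt(lam_hi / (df * n))))


# ---------------------------------------------------------------------------
# EM for multivariate-normal moments under missingness
# ---------------------------------------------------------------------------

def em_normal_estimates(data: pd.DataFrame, max_iter: int = 500,
                        tol: float = 1e-8
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """EM estimates of the MVN mean and covariance with missing entries.

    Returns ``(mu, sigma, info)``; ``sigma`` is the ML (divisor n)
    covariance.  With no missing data this equals the sample moments after
    a single E-step.  A fully missing variable, or non-convergence within
    ``max_iter``, raises with a trace of the objective.
    """
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        cols = list(data.columns[miss.all(axis=0)])
        raise ValueError(f"variable(s) fully missing: {cols}")
    keep = ~miss.all(axis=1)
    X, miss = X[keep], miss[keep]
    n = X.shape[0]

    mu = np.nanmean(X, axis=0)
    diffs = np.where(miss, 0.0, X - mu)
    sigma = np.cov(np.where(miss, np.nan, X).T, ddof=0)
    sigma = np.where(np.isnan(sigma), 0.0, sigma)
    sigma += np.eye(p) * 1e-6

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)

    trace = []
    for it in range(max_iter):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for key, idx in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            o = ~m
            rows = X[idx]
            if not m.any():
                S1 += rows.sum(axis=0)
                S2 += rows.T @ rows
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            W = np.linalg.solve(Soo, Smo.T).T           # regression weights
            cond_cov = sigma[np.ix_(m, m)] - W @ Smo.T
            xo = rows[:, o]
            xm_hat = mu[m] + (xo - mu[o]) @ W.T
            filled = rows.copy()
            filled[:, m] = xm_hat
            S1 += filled.sum(axis=0)
            S2 += filled.T @ filled
            C = np.zeros((p, p))
            C[np.ix_(m, m)] = cond_cov * len(idx)
            S2 += C
        mu_new = S1 / n
        sigma_new = S2 / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(),
                    np.abs(sigma_new - sigma).max())
        trace.append(delta)
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            return mu, sigma, {"n_iter": it + 1, "converged": True,
                               "trace": trace, "n_used": n}
    raise RuntimeError(f"EM did not converge in {max_iter} iterations; "
                       f"last deltas: {trace[-5:]}")
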
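"""Mediation machinery: path algebra, bootstrap behaviour, fit indices and
EM-based missing-data estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drisk.mediation import (MediationSpec, bootstrap, em_normal_estimates,
                             fit_indices, fit_indices_from_chi2,
                             fit_mediation)
from drisk.simulate import simulate_mediation_panel

SPEC_COLS = dict(x="x", m_bl="m_bl", m_fu="m_fu", y_bl="y_bl", y_fu="y_fu")


def spec(**kw):
    return MediationSpec(**SPEC_COLS, **kw)


def exact_linear_panel():
    """Deterministic panel with exact linear relations (no residuals)."""
    x = np.array([0, 0, 0, 1, 1, 1, 0, 1], dtype=float)
    m_bl = np.array([-1, 0, 1, -1, 0, 1, 2, 2], dtype=float)
    y_bl = np.array([1, -1, 0, 1, -1, 0, -2, -2], dtype=float)
    m_fu = 0.5 * x + 0.3 * m_bl
    y_fu = -0.2 * x + 0.4 * m_fu + 0.6 * y_bl
    return pd.DataFrame({"x": x, "m_bl": m_bl, "m_fu": m_fu,
                         "y_bl": y_bl, "y_fu": y_fu})


def test_exact_linear_relations_recovered_unstandardized_scale():
    # verify the path algebra itself on the covariance of the raw data
    from drisk.mediation import _paths_from_cov
    df = exact_linear_panel()
    S = np.cov(df[["x", "m_bl", "y_bl", "m_fu", "y_fu"]].to_numpy().T)
    p = _paths_from_cov(S, include_m_bl_in_y=False)
    assert p["a"] == pytest.approx(0.5, abs=1e-10)
    assert p["b"] == pytest.approx(0.4, abs=1e-10)
    assert p["c_prime"] == pytest.approx(-0.2, abs=1e-10)
    # constructed X ⊥ M_bl, so the separately regressed total effect
    # matches the a·b + c′ decomposition on this zero-residual panel
    assert p["c_marginal"] == pytest.approx(
        p["a"] * p["b"] + p["c_prime"], abs=1e-9)


def test_fit_mediation_null_mediator_covers_zero():
    rng = np.random.default_rng(3)
    n = 1500
    x = (rng.random(n) < 0.5).astype(float)
    m_bl = rng.normal(0, 1, n)
    m_fu = 0.4 * m_bl + rng.normal(0, 1, n)          # b = 0 and a = 0
    y_bl = rng.normal(0, 1, n)
    y_fu = -0.2 * x + 0.5 * y_bl + rng.normal(0, 1, n)
    df = pd.DataFrame({"x": x, "m_bl": m_bl, "m_fu": m_fu,
                       "y_bl": y_bl, "y_fu": y_fu})
    res = fit_mediation(df, spec(n_boot=400, seed=1))
    ci = res.boot["indirect"]
    assert ci["ci_low"] <= 0 <= ci["ci_high"]
    assert abs(res.proportion_mediated) < 30  # tiny indirect share


def test_additivity_total_equals_direct_plus_indirect():
    df = simulate_mediation_panel(800, a=0.3, b=-0.2, c_prime=-0.1, seed=4)
    res = fit_mediation(df, spec(n_boot=50, seed=4))
    assert res.c == pytest.approx(res.indirect + res.c_prime, abs=1e-12)


def test_inconsistent_mediation_flagged():
    df = simulate_mediation_panel(4000, a=0.5, b=0.3, c_prime=-0.12, seed=9)
    res = fit_mediation(df, spec(n_boot=20, seed=9))
    assert res.inconsistent_mediation


def test_zero_variance_exposure_raises():
    df = exact_linear_panel()
    df["x"] = 1.0
    with pytest.raises(ValueError, match="zero variance"):
        fit_mediation(df, spec(n_boot=5, seed=0))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_given_seed():
    df = simulate_mediation_panel(300, a=0.3, b=-0.1, c_prime=-0.1, seed=6)
    r1 = fit_mediation(df, spec(n_boot=60, seed=42))
    r2 = fit_mediation(df, spec(n_boot=60, seed=42))
    assert r1.boot["indirect"] == r2.boot["indirect"]


def test_bootstrap_se_of_mean_matches_closed_form():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"v": rng.normal(0, 1, 400)})
    out = bootstrap(df, spec(n_boot=600, seed=5), lambda d: d["v"].mean(),
                    n_boot=600, seed=5)
    se = out["stats"]["stat"]["se"]
    assert abs(se - 1 / 20) < 0.15 / 20  # within 15% of 1/sqrt(400)


def test_single_replicate_se_undefined():
    df = pd.DataFrame({"v": np.arange(20.0)})
    out = bootstrap(df, spec(n_boot=1, seed=2), lambda d: d["v"].mean(),
                    n_boot=1, seed=2)
    assert not out["stats"]["stat"]["se_defined"]
    assert np.isnan(out["stats"]["stat"]["se"])


def test_failing_resamples_redrawn_and_counted():
    df = pd.DataFrame({"v": np.arange(30.0)})
    calls = {"n": 0}

    def flaky(d):
        calls["n"] += 1
        if calls["n"] % 3 == 0:
            raise RuntimeError("boom")
        return d["v"].mean()

    out = bootstrap(df, spec(n_boot=30, seed=3), flaky, n_boot=30, seed=3)
    assert out["n_failures"] > 0
    assert len(out["draws"]["stat"]) == 30


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def independent_fit_indices(chi2_m, df_m, chi2_b, df_b, n):
    """Textbook formulas, implemented separately from the package."""
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1 - num / den
    rmsea = 0.0 if df_m == 0 else (num / (df_m * n)) ** 0.5
    return cfi, rmsea


def test_perfect_fit_limits():
    cfi, rmsea, ci = fit_indices_from_chi2(10.0, 10, 500.0, 15, 1000)
    assert cfi == 1.0 and rmsea == 0.0
    assert ci[0] == 0.0
    # χ² below df behaves the same
    cfi, rmsea, _ = fit_indices_from_chi2(4.0, 10, 500.0, 15, 1000)
    assert cfi == 1.0 and rmsea == 0.0


def test_no_improvement_over_baseline_cfi_zero():
    cfi, _, _ = fit_indices_from_chi2(80.0, 10, 80.0, 10, 500)
    assert cfi == 0.0


def test_rmsea_formula_value():
    # χ² = 2·df, df = 10, n = 1000 → √(10/10000) ≈ 0.0316
    _, rmsea, _ = fit_indices_from_chi2(20.0, 10, 900.0, 15, 1000)
    assert rmsea == pytest.approx(np.sqrt(10 / 10000), abs=1e-12)


def test_fit_indices_from_logliks():
    cfi, rmsea, _ = fit_indices(loglik_model=-500.0, loglik_saturated=-490.0,
                                loglik_baseline=-700.0, df_model=10,
                                df_baseline=15, n=1000)
    expect_cfi, expect_rmsea = independent_fit_indices(20.0, 10, 420.0, 15, 1000)
    assert cfi == pytest.approx(expect_cfi)
    assert rmsea == pytest.approx(expect_rmsea)


def test_index_formula_agreement_on_random_tuples():
    rng = np.random.default_rng(17)
    for _ in range(20):
        df_m = int(rng.integers(1, 30))
        df_b = df_m + int(rng.integers(1, 20))
        chi2_m = float(rng.uniform(0, 4) * df_m)
        chi2_b = chi2_m + float(rng.uniform(0, 50))
        n = int(rng.integers(50, 5000))
        cfi, rmsea, ci = fit_indices_from_chi2(chi2_m, df_m, chi2_b, df_b, n)
        ecfi, ermsea = independent_fit_indices(chi2_m, df_m, chi2_b, df_b, n)
        assert cfi == pytest.approx(ecfi, abs=1e-12)
        assert rmsea == pytest.approx(ermsea, abs=1e-12)
        assert 0 <= ci[0] <= rmsea + 1e-12 <= ci[1] + 1e-9


def test_rmsea_ci_brackets_known_quantiles():
    # the CI endpoints must invert the noncentral χ²: check directly
    chi2, df, n = 45.0, 20, 800
    _, rmsea, (lo, hi) = fit_indices_from_chi2(chi2, df, 500.0, 25, n)
    lam_lo = lo**2 * df * n
    lam_hi = hi**2 * df * n
    assert stats.ncx2.cdf(chi2, df, lam_hi) == pytest.approx(0.05, abs=1e-6)
    assert stats.ncx2.cdf(chi2, df, max(lam_lo, 1e-10)) == pytest.approx(
        0.95, abs=1e-6) or lo == 0.0


# ---------------------------------------------------------------------------
# EM under missingness
# ---------------------------------------------------------------------------

def test_em_equals_sample_moments_without_missingness():
    rng = np.random.default_rng(21)
    df = pd.DataFrame(rng.normal(0, 1, (300, 4)), columns=list("abcd"))
    mu, sigma, info = em_normal_estimates(df)
    assert np.allclose(mu, df.mean().values, atol=1e-8)
    assert np.allclose(sigma, np.cov(df.to_numpy().T, ddof=0), atol=1e-8)


def test_em_complete_case_equivalence_in_paths():
    df = simulate_mediation_panel(2000, a=0.41, b=-0.05, c_prime=-0.11, seed=8)
    cc = fit_mediation(df, spec(n_boot=10, seed=8))
    em = fit_mediation(df, spec(n_boot=10, seed=8, missing="em_normal"))
    assert em.a == pytest.approx(cc.a, abs=1e-6)
    assert em.b == pytest.approx(cc.b, abs=1e-6)
    assert em.c_prime == pytest.approx(cc.c_prime, abs=1e-6)


def test_em_recovers_truth_under_mcar():
    reps = 12
    a_hat = np.empty(reps)
    for r in range(reps):
        df = simulate_mediation_panel(2000, a=0.41, b=-0.05, c_prime=-0.11,
                                      seed=100 + r)
        rng = np.random.default_rng(200 + r)
        for c in ("m_bl", "m_fu", "y_bl", "y_fu"):
            df.loc[rng.random(len(df)) < 0.2, c] = np.nan
        res = fit_mediation(df, spec(n_boot=1, seed=r, missing="em_normal"))
        a_hat[r] = res.a
    mc_se = a_hat.std(ddof=1) / np.sqrt(reps)
    assert abs(a_hat.mean() - 0.41) < max(3 * mc_se, 0.02)


def test_em_fully_missing_variable_raises():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="fully missing"):
        em_normal_estimates(df)


def test_spec_validation():
    with pytest.raises(ValueError):
        MediationSpec(**SPEC_COLS, n_boot=0)
    with pytest.raises(ValueError):
        MediationSpec(**SPEC_COLS, missing="oops")
    with pytest.raises(ValueError):
        MediationSpec(x="x", m_bl="m", m_fu="m", y_bl="y_bl", y_fu="y_fu")
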
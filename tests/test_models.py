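"""Mixed-model machinery: standardization identities, marginal means,
Tukey adjustment, multinomial transitions and R² decomposition."""

import numpy as np
import pandas as pd
import pytest

from drisk.cohort import build_panel, continuous_model_input
from drisk.models import (fit_trajectory, fit_transitions, marginal_means,
                          marginal_r2, tukey_contrasts)


@pytest.fixture(scope="module")
def fitted(small_panel):
    panel = continuous_model_input(small_panel)
    return fit_trajectory(panel), panel


def toy_panel(n=60, waves=3, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        u = rng.normal(0, 1)
        for w in range(waves):
            rows.append({
                "participant_id": f"p{i}", "n_drp_exposures": w,
                "log_time": np.log(12 * w + 1), "pdmooc": i % 2,
                "drp_total": 2 + u + effect * w + rng.normal(0, 0.5)})
    return pd.DataFrame(rows)


def test_standardized_coefficient_identity(fitted):
    res, panel = fitted
    # b_s = b·SD(x)/SD(y) for the continuous exposure-count term
    sd_y = panel.loc[panel.index.isin(res.data.index), "drp_total"].std()
    X = np.asarray(res.fitted.model.exog)
    j = res.fitted.model.exog_names.index("n_drp_exposures")
    sd_x = X[:, j].std(ddof=1)
    sd_y = np.asarray(res.fitted.model.endog).std(ddof=1)
    expect = res.params["n_drp_exposures"] * sd_x / sd_y
    assert res.standardized.loc["n_drp_exposures", "b_s"] == pytest.approx(expect)
    # binary predictor scaled by 1/SD(y) only
    expect_b = res.params["pdmooc"] / sd_y
    assert res.standardized.loc["pdmooc", "b_s"] == pytest.approx(expect_b)


def test_standardization_matches_refit_on_zscored_data():
    panel = toy_panel(n=80, seed=2, effect=-0.2)
    res = fit_trajectory(panel, include_pdmooc=False, interaction=False,
                         time_term=False)
    z = panel.copy()
    for c in ("drp_total", "n_drp_exposures"):
        z[c] = (z[c] - z[c].mean()) / z[c].std()
    res_z = fit_trajectory(z, include_pdmooc=False, interaction=False,
                           time_term=False)
    assert res.standardized.loc["n_drp_exposures", "b_s"] == pytest.approx(
        res_z.params["n_drp_exposures"], abs=1e-6)


def test_emm_intercept_only_is_grand_mean():
    panel = toy_panel(n=40, seed=3)
    res = fit_trajectory(panel, exposure_term=False, time_term=False,
                         include_pdmooc=False, interaction=False)
    grid = pd.DataFrame({"n_drp_exposures": [0, 1, 2]})
    emm = marginal_means(res, grid)
    mean_hat = res.params["Intercept"]
    assert np.allclose(emm["emm"], mean_hat)


def test_emm_balanced_design_equals_cell_means():
    # balanced one-factor layout, no random structure to speak of
    rng = np.random.default_rng(7)
    rows = []
    cell = {0: 1.0, 1: 2.5, 2: 4.0}
    for i in range(90):
        w = i % 3
        rows.append({"participant_id": f"p{i // 3}",
                     "n_drp_exposures": w, "log_time": 0.0, "pdmooc": 0,
                     "drp_total": cell[w] + rng.normal(0, 0.05)})
    panel = pd.DataFrame(rows)
    res = fit_trajectory(panel, time_term=False, include_pdmooc=False,
                         interaction=False)
    emm = marginal_means(res, pd.DataFrame({"n_drp_exposures": [0, 1, 2]}))
    # linear-in-w fit on exactly linear cell means reproduces them
    assert np.allclose(emm["emm"], [1.0, 2.5, 4.0], atol=0.05)


def test_tukey_contrast_count_and_monotonicity(fitted):
    res, _ = fitted
    grid = pd.DataFrame({"n_drp_exposures": [0, 1, 2, 3]})
    tk = tukey_contrasts(res, grid)
    assert len(tk) == 6  # C(4, 2) pairwise contrasts
    assert (tk["p_tukey"] >= tk["p_unadjusted"] - 1e-12).all()
    assert (tk["p_tukey"] <= 1.0).all()


def test_grid_term_absent_raises(fitted):
    res, _ = fitted
    with pytest.raises(ValueError, match="not in the fitted model"):
        marginal_means(res, pd.DataFrame({"no_such_term": [1]}))


def test_single_wave_input_raises():
    panel = toy_panel(waves=1)
    with pytest.raises(ValueError, match="single-wave"):
        fit_trajectory(panel, time_term=False, include_pdmooc=False,
                       interaction=False)


def test_too_few_participants_raises():
    panel = toy_panel(n=1)
    with pytest.raises(ValueError, match="2 participants"):
        fit_trajectory(panel)


def test_collinear_terms_named():
    panel = toy_panel(n=30)
    panel["dup"] = panel["n_drp_exposures"]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_trajectory(panel, covariates=("dup",), include_pdmooc=False,
                       interaction=False, time_term=False)


def test_marginal_r2_null_and_limit():
    panel = toy_panel(n=60, seed=5, effect=0.0)
    res = fit_trajectory(panel, exposure_term=False, time_term=False,
                         include_pdmooc=False, interaction=False)
    r2m, r2c = marginal_r2(res)
    assert r2m == pytest.approx(0.0, abs=1e-10)   # intercept-only fixed part
    assert 0 <= r2m <= r2c <= 1
    # no between-person variance: marginal ≈ conditional
    rng = np.random.default_rng(8)
    flat = toy_panel(n=80, seed=8, effect=-0.3)
    flat["drp_total"] = (2 - 0.3 * flat["n_drp_exposures"]
                         + rng.normal(0, 0.5, len(flat)))
    res2 = fit_trajectory(flat, time_term=False, include_pdmooc=False,
                          interaction=False)
    assert res2.r2_conditional - res2.r2_marginal < 0.05


def test_r2_with_known_variance_components():
    # y = b·x + u + e with known variances: analytic R² = var_f/(tot)
    rng = np.random.default_rng(12)
    n, w = 400, 3
    b, su, se_ = 0.5, 1.0, 0.7
    rows = []
    for i in range(n):
        u = rng.normal(0, su)
        for k in range(w):
            rows.append({"participant_id": i, "n_drp_exposures": k,
                         "log_time": 0.0, "pdmooc": 0,
                         "drp_total": b * k + u + rng.normal(0, se_)})
    res = fit_trajectory(pd.DataFrame(rows), time_term=False,
                         include_pdmooc=False, interaction=False)
    var_f = b**2 * np.var([0, 1, 2])
    expect = var_f / (var_f + su**2 + se_**2)
    assert res.r2_marginal == pytest.approx(expect, abs=0.04)


def test_reml_fit_matches_lme4_oracle(small_panel, tmp_path):
    """Fixed effects and variance components agree with an independent
    lme4 REML fit of the same model on the same panel."""
    import subprocess
    panel = continuous_model_input(small_panel)
    cols = ["participant_id", "drp_total", "n_drp_exposures", "log_time",
            "pdmooc"]
    csv = tmp_path / "panel.csv"
    panel[cols].to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        'suppressMessages(library(lme4))\n'
        'args <- commandArgs(trailingOnly=TRUE)\n'
        'd <- read.csv(args[1])\n'
        'm <- lmer(drp_total ~ n_drp_exposures + log_time + pdmooc '
        '+ n_drp_exposures:pdmooc + (1|participant_id), data=d, REML=TRUE)\n'
        'fe <- fixef(m)\n'
        'vc <- as.data.frame(VarCorr(m))\n'
        'write.csv(data.frame(term=names(fe), estimate=as.numeric(fe)), '
        'args[2], row.names=FALSE)\n'
        'write.csv(vc[, c("grp", "vcov")], args[3], row.names=FALSE)\n')
    fe_csv, vc_csv = tmp_path / "fe.csv", tmp_path / "vc.csv"
    subprocess.run(["Rscript", str(rscript), str(csv), str(fe_csv),
                    str(vc_csv)], check=True, capture_output=True)
    fe = pd.read_csv(fe_csv).set_index("term")["estimate"]
    vc = pd.read_csv(vc_csv).set_index("grp")["vcov"]
    res = fit_trajectory(panel)
    assert res.params["Intercept"] == pytest.approx(fe["(Intercept)"], abs=1e-4)
    for t in ("n_drp_exposures", "log_time", "pdmooc",
              "n_drp_exposures:pdmooc"):
        assert res.params[t] == pytest.approx(fe[t], abs=1e-4)
    assert res.var_random_intercept == pytest.approx(
        vc["participant_id"], abs=1e-3)
    assert res.var_residual == pytest.approx(vc["Residual"], abs=1e-3)


# ---------------------------------------------------------------------------
# multinomial transitions
# ---------------------------------------------------------------------------

def test_transition_intercept_only_matches_proportions():
    bl = pd.Series(["low"] * 200)
    fin = pd.Series(["low"] * 120 + ["medium"] * 50 + ["high"] * 30)
    res = fit_transitions(bl, fin)
    probs = res.predicted_probabilities()[0]
    assert np.allclose(probs, [0.6, 0.25, 0.15], atol=1e-6)


def test_transition_collapsed_odds_ratio_hand_computed():
    # 2×2 table a=40 b=10 c=20 d=30 → OR = (40·30)/(10·20) = 6
    bl = pd.Series(["high"] * 50 + ["low"] * 50)
    fin = pd.Series(["high"] * 40 + ["low"] * 10 + ["high"] * 20 + ["low"] * 30)
    res = fit_transitions(bl, fin, collapse_binary=True)
    or_row = res.odds_ratios.query("term == 'baseline_elevated'")
    assert or_row["odds_ratio"].iloc[0] == pytest.approx(6.0, rel=1e-4)


def test_transition_no_change_perfect_prediction():
    levels = ["low"] * 60 + ["medium"] * 25 + ["high"] * 15
    bl = pd.Series(levels)
    res = fit_transitions(bl, bl.copy())
    pred = res.predicted_probabilities().argmax(axis=1)
    codes = pd.Categorical(bl[bl != "unknown"],
                           categories=res.categories).codes
    assert (pred == codes).mean() == 1.0


def test_transition_empty_category_with_covariates_raises():
    bl = pd.Series(["low"] * 30 + ["medium"] * 30 + ["high"] * 30)
    fin = pd.Series(["low"] * 60 + ["medium"] * 30)  # no 'high' at follow-up
    cov = pd.DataFrame({"age": np.linspace(50, 80, 90)})
    with pytest.raises(ValueError, match="collaps"):
        fit_transitions(bl, fin, covariates=cov)


def test_transitions_on_simulated_panel(small_panel):
    from drisk.models import fit_all_transitions
    results = fit_all_transitions(small_panel)
    assert set(results) == set(
        ["alcohol", "bmi", "hypertension", "cholesterol", "diabetes",
         "smoking", "cognitive_activity", "physical_activity", "diet"])
    for res in results.values():
        ors = res.odds_ratios
        assert (ors["odds_ratio"] > 0).all()
        ok = ors["or_low"].notna() & ors["or_high"].notna()
        assert (ors.loc[ok, "or_low"] <= ors.loc[ok, "odds_ratio"] + 1e-9).all()
        assert (ors.loc[ok, "or_high"] >= ors.loc[ok, "odds_ratio"] - 1e-9).all()
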
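"""Outlier razor, trial model, heritability, MPH, GCA/SCA and path analysis."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from nciiqtl._reml import factor_kernel
from nciiqtl.phenostats import (
    broad_sense_heritability,
    compute_mph,
    correlations_and_path,
    fit_trial_model,
    gca_sca_decompose,
    mph_model,
    mph_table,
    remove_outliers,
    summarize_trait,
    within_env_blue,
)

from conftest import balanced_trial_records


# ---------------------------------------------------------------------------
# outlier razor

def test_homogeneous_data_no_removals():
    rec = balanced_trial_records(n_geno=15, s2_g=4.0, s2_gxe=0.0, s2_rep=0.0,
                                 s2_e=1.0, seed=1)
    clean, log = remove_outliers(rec)
    assert len(log) == 0
    assert len(clean) == len(rec)


def test_injected_gross_outlier_removed():
    rec = balanced_trial_records(n_geno=20, s2_g=4.0, s2_gxe=1.0, s2_rep=0.5,
                                 s2_e=1.0, seed=2)
    rec.loc[17, "value"] += 20.0  # ~20 SD shift
    clean, log = remove_outliers(rec)
    assert len(log) == 1
    assert log.iloc[0]["genotype"] == rec.loc[17, "genotype"]
    assert log.iloc[0]["environment"] == rec.loc[17, "environment"]
    assert len(clean) == len(rec) - 1


def test_threshold_is_strict():
    """A residual exactly at the threshold is retained (strict inequality)."""
    rng = np.random.default_rng(3)
    rec = balanced_trial_records(n_geno=12, s2_g=2.0, s2_gxe=0.5, s2_rep=0.2,
                                 s2_e=1.0, seed=4)
    clean_hi, log_hi = remove_outliers(rec, threshold=np.inf)
    assert len(log_hi) == 0
    # threshold equal to the largest |t|: that record is retained (strict >)
    _, log_all = remove_outliers(rec, threshold=0.0)
    tmax = log_all["studentized_residual"].abs().max()
    _, log_at = remove_outliers(rec, threshold=tmax)
    assert len(log_at) == 0


# ---------------------------------------------------------------------------
# trial model and heritability

def test_balanced_noiseless_blues_are_marginal_means():
    rec = balanced_trial_records(n_geno=10, s2_g=9.0, s2_gxe=0.0, s2_rep=0.0,
                                 s2_e=0.0, seed=5)
    res = fit_trial_model(rec)
    marginal = rec.groupby("genotype")["value"].mean()
    pd.testing.assert_series_equal(
        res.blues.sort_index(), marginal.sort_index(),
        check_names=False, atol=1e-6,
    )
    # numerically zero relative to the genetic variance of 9
    assert res.variances["residual"] < 1e-4


def test_trial_varcomp_recovery():
    """(sigma2_G, sigma2_GxE, sigma2_e) = (10, 4, 8) recovered on average."""
    truth = {"genotype": 10.0, "gxe": 4.0, "residual": 8.0}
    est = {k: [] for k in truth}
    for seed in range(5):
        rec = balanced_trial_records(n_geno=80, n_env=4, n_rep=2, s2_g=10.0,
                                     s2_gxe=4.0, s2_rep=1.0, s2_e=8.0, seed=seed)
        res = fit_trial_model(rec)
        for k in truth:
            est[k].append(res.variances[k])
    for k, target in truth.items():
        assert np.mean(est[k]) == pytest.approx(target, rel=0.20)


def brute_force_reml(y, X, kernels):
    """Independent oracle: REML criterion assembled from its definition and
    optimized over raw variances with Nelder-Mead."""
    n, p = X.shape

    def negloglik(log_s2):
        s2 = np.exp(log_s2)
        V = s2[-1] * np.eye(n)
        for sv, K in zip(s2[:-1], kernels):
            V += sv * K
        Vi = np.linalg.inv(V)
        _, ld_V = np.linalg.slogdet(V)
        XtViX = X.T @ Vi @ X
        _, ld_X = np.linalg.slogdet(XtViX)
        b = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ b
        return 0.5 * (ld_V + ld_X + r @ Vi @ r)

    best = None
    for x0 in (np.zeros(len(kernels) + 1), np.full(len(kernels) + 1, 1.5)):
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x)


def test_trial_model_matches_brute_force_ml_oracle():
    rec = balanced_trial_records(n_geno=12, n_env=3, n_rep=2, s2_g=10.0,
                                 s2_gxe=4.0, s2_rep=2.0, s2_e=8.0, seed=3)
    res = fit_trial_model(rec)
    y = rec["value"].to_numpy()
    env = rec["environment"].to_numpy()
    X = np.column_stack([np.ones(len(rec)),
                         pd.get_dummies(env).to_numpy(dtype=float)[:, 1:]])
    kernels = [
        factor_kernel(rec["genotype"]),
        factor_kernel(rec["genotype"].astype(str) + "@" + rec["environment"].astype(str)),
        factor_kernel(rec["environment"].astype(str) + ":" + rec["replicate"].astype(str)),
    ]
    oracle = brute_force_reml(y, X, kernels)
    assert res.variances["genotype"] == pytest.approx(oracle[0], abs=1e-4, rel=1e-4)
    assert res.variances["gxe"] == pytest.approx(oracle[1], abs=1e-4, rel=1e-4)
    assert res.variances["residual"] == pytest.approx(oracle[3], abs=1e-4, rel=1e-4)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_trial_model_matches_lme4(tmp_path):
    """Cross-check the REML engine against lme4 on a balanced instance."""
    rec = balanced_trial_records(n_geno=25, n_env=3, n_rep=2, s2_g=10.0,
                                 s2_gxe=4.0, s2_rep=2.0, s2_e=8.0, seed=3)
    rec.to_csv(tmp_path / "rec.tsv", sep="\t", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        'library(lme4)\n'
        f'd <- read.delim("{tmp_path / "rec.tsv"}")\n'
        'd$er <- interaction(d$environment, d$replicate)\n'
        'fit <- lmer(value ~ environment + (1|genotype) + (1|genotype:environment)'
        ' + (1|er), data=d, REML=TRUE)\n'
        'vc <- as.data.frame(VarCorr(fit))\n'
        'cat(vc$vcov[vc$grp=="genotype"], vc$vcov[vc$grp=="genotype:environment"],'
        ' vc$vcov[vc$grp=="Residual"], sep="\\n")\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         check=True)
    vg, vgxe, ve = (float(x) for x in out.stdout.strip().split("\n"))
    res = fit_trial_model(rec)
    assert res.variances["genotype"] == pytest.approx(vg, rel=1e-3)
    assert res.variances["gxe"] == pytest.approx(vgxe, rel=1e-3)
    assert res.variances["residual"] == pytest.approx(ve, rel=1e-3)


def test_single_environment_gxe_flagged():
    rec = balanced_trial_records(n_geno=10, n_env=1, s2_gxe=0.0, seed=6)
    with pytest.warns(UserWarning, match="single environment"):
        res = fit_trial_model(rec)
    assert not res.gxe_estimable


@pytest.mark.parametrize(
    "sg,sgxe,se,ne,nr,expected",
    [
        (217.97, 26.64, 45.08, 4, 2, 0.95),
        (40.76, 45.49, 180.99, 5, 2, 0.60),
        (10.0, 0.0, 0.0, 3, 2, 1.0),
    ],
)
def test_broad_sense_heritability(sg, sgxe, se, ne, nr, expected):
    assert round(broad_sense_heritability(sg, sgxe, se, ne, nr), 2) == expected


def test_heritability_undefined_when_all_zero():
    with pytest.warns(UserWarning, match="undefined"):
        h = broad_sense_heritability(0.0, 0.0, 0.0, 4, 2)
    assert np.isnan(h)


def test_heritability_in_unit_interval():
    rng = np.random.default_rng(11)
    for _ in range(100):
        sg, sgxe, se = rng.exponential(10, size=3)
        h = broad_sense_heritability(sg, sgxe, se, 4, 2)
        assert 0.0 <= h <= 1.0


@pytest.mark.parametrize(
    "mean,sd,cv",
    [(179.28, 15.29, 8.53), (67.87, 8.91, 13.13)],
)
def test_cv_closed_form(mean, sd, cv):
    assert round(100.0 * sd / mean, 2) == cv


def test_summarize_trait():
    s = summarize_trait([2.0, 4.0, 6.0])
    assert s["min"] == 2.0 and s["max"] == 6.0 and s["mean"] == 4.0
    assert s["CV"] == pytest.approx(100.0 * s["SD"] / 4.0)
    const = summarize_trait([3.0, 3.0, 3.0])
    assert const["SD"] == 0.0 and const["CV"] == 0.0
    with pytest.warns(UserWarning, match="CV undefined"):
        s0 = summarize_trait([-1.0, 1.0])
    assert np.isnan(s0["CV"])


# ---------------------------------------------------------------------------
# within-environment BLUEs and MPH

def test_within_env_blue_no_rep_effect_is_rep_mean():
    rec = balanced_trial_records(n_geno=8, n_env=1, n_rep=2, s2_g=5.0,
                                 s2_gxe=0.0, s2_rep=0.0, s2_e=0.5, seed=7)
    blue = within_env_blue(rec)
    means = rec.groupby("genotype")["value"].mean()
    np.testing.assert_allclose(blue.sort_index(), means.sort_index(), atol=0.02)


def test_within_env_blue_single_replicate_is_observation():
    rec = balanced_trial_records(n_geno=6, n_env=1, n_rep=1, s2_e=1.0, seed=8)
    blue = within_env_blue(rec)
    obs = rec.set_index("genotype")["value"]
    np.testing.assert_allclose(blue.sort_index(), obs.sort_index())


def test_within_env_blue_balanced_shift_invariance():
    """Adding a constant to one replicate block shifts every BLUE equally
    (balanced design: the replicate effect is absorbed symmetrically)."""
    rec = balanced_trial_records(n_geno=10, n_env=1, n_rep=2, s2_g=5.0,
                                 s2_rep=1.0, s2_e=1.0, seed=9)
    blue1 = within_env_blue(rec)
    rec2 = rec.copy()
    rec2.loc[rec2["replicate"] == "r0", "value"] += 7.0
    blue2 = within_env_blue(rec2)
    diff = (blue2 - blue1).to_numpy()
    np.testing.assert_allclose(diff, diff[0] * np.ones_like(diff), atol=1e-8)


def test_compute_mph():
    assert compute_mph(10.0, 8.0, 6.0) == pytest.approx(3.0)
    assert compute_mph(7.0, 8.0, 6.0) == pytest.approx(0.0)
    c = 12.3
    assert compute_mph(10 + c, 8 + c, 6 + c) == pytest.approx(compute_mph(10, 8, 6))
    assert np.isnan(compute_mph(10.0, np.nan, 6.0))


def test_mph_table_missing_parent_gives_nan():
    blues = pd.DataFrame({
        "genotype": ["H1", "P1", "H1", "P1", "P2"],
        "environment": ["e0", "e0", "e1", "e1", "e0"],
        "value": [10.0, 8.0, 12.0, 9.0, 6.0],
    })
    tbl = mph_table(blues, {"H1": ("P1", "P2")})
    e0 = tbl[tbl["environment"] == "e0"]["value"].iloc[0]
    e1 = tbl[tbl["environment"] == "e1"]["value"].iloc[0]
    assert e0 == pytest.approx(10.0 - 7.0)
    assert np.isnan(e1)


def _mph_records(n_hyb, n_env, s2_g, s2_e, seed, s2_env=2.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2_g), n_hyb)
    e = rng.normal(0, np.sqrt(s2_env), n_env)
    rows = []
    for i in range(n_hyb):
        for j in range(n_env):
            rows.append({"genotype": f"h{i:03d}", "environment": f"e{j}",
                         "value": g[i] + e[j] + rng.normal(0, np.sqrt(s2_e))})
    return pd.DataFrame(rows)


def test_mph_model_zero_signal():
    rec = _mph_records(60, 4, s2_g=0.0, s2_e=1.0, seed=10)
    res = mph_model(rec)
    assert res.variances["genotype"] < 0.1


def test_mph_model_recovery():
    est_g = []
    for seed in range(5):
        rec = _mph_records(150, 4, s2_g=2.0, s2_e=1.0, seed=seed)
        res = mph_model(rec)
        est_g.append(res.variances["genotype"])
    assert np.mean(est_g) == pytest.approx(2.0, rel=0.2)


def test_mph_model_matches_brute_force():
    rec = _mph_records(10, 3, s2_g=2.0, s2_e=1.0, seed=12)
    res = mph_model(rec)
    y = rec["value"].to_numpy()
    X = np.ones((len(y), 1))
    kernels = [factor_kernel(rec["genotype"]), factor_kernel(rec["environment"])]
    oracle = brute_force_reml(y, X, kernels)
    assert res.variances["genotype"] == pytest.approx(oracle[0], abs=1e-4, rel=1e-4)
    assert res.variances["env"] == pytest.approx(oracle[1], abs=1e-4, rel=1e-4)
    assert res.variances["residual"] == pytest.approx(oracle[2], abs=1e-4, rel=1e-4)


def test_mph_model_single_environment_rejected():
    rec = _mph_records(10, 1, s2_g=1.0, s2_e=1.0, seed=13)
    with pytest.raises(ValueError, match="two environments"):
        mph_model(rec)


def test_mph_heritability_formula():
    rec = _mph_records(120, 4, s2_g=2.0, s2_e=0.5, seed=14)
    res = mph_model(rec)
    expected = res.variances["genotype"] / (
        res.variances["genotype"] + res.variances["residual"] / 4
    )
    assert res.heritability == pytest.approx(expected)
    assert 0.0 <= res.heritability <= 1.0


# ---------------------------------------------------------------------------
# GCA / SCA

def _ncii_values(n_ril, s2_gr, s2_gt, s2_sca, s2_e, seed, n_env=3):
    rng = np.random.default_rng(seed)

    def _exact_var(v, target):
        v = v - v.mean()
        sd = v.std()
        return v * np.sqrt(target) / sd if sd > 0 and target > 0 else v * 0.0

    g = _exact_var(rng.normal(size=n_ril), s2_gr)
    t = _exact_var(rng.normal(size=2), s2_gt)
    s = _exact_var(rng.normal(size=(n_ril, 2)).ravel(), s2_sca).reshape(n_ril, 2)
    env = rng.normal(0, 1.0, n_env)
    rows = []
    for i in range(n_ril):
        for j in range(2):
            for k in range(n_env):
                rows.append({
                    "ril": f"r{i:03d}", "tester": f"T{j+1}", "environment": f"e{k}",
                    "value": 100 + g[i] + t[j] + s[i, j] + env[k]
                    + rng.normal(0, np.sqrt(s2_e)),
                })
    return pd.DataFrame(rows)


def test_gca_sca_additive_hybrids_have_no_sca():
    df = _ncii_values(40, s2_gr=2.0, s2_gt=1.0, s2_sca=0.0, s2_e=0.3, seed=15)
    res = gca_sca_decompose(df)
    assert res.variances["sca"] < 0.1
    assert res.sca_gca_ratio < 0.1


def test_gca_sca_ratio_recovery():
    # sigma2_SCA / (sigma2_GCA_RIL + sigma2_GCA_Tester) = 0.5 by construction
    ratios = []
    for seed in range(10):
        df = _ncii_values(60, s2_gr=1.2, s2_gt=0.8, s2_sca=1.0, s2_e=0.4, seed=seed)
        res = gca_sca_decompose(df)
        ratios.append(res.sca_gca_ratio)
    assert np.mean(ratios) == pytest.approx(0.5, rel=0.25)


def test_gca_sca_single_tester_rejected():
    df = _ncii_values(10, 1.0, 0.5, 0.5, 0.3, seed=16)
    df = df[df["tester"] == "T1"]
    with pytest.raises(ValueError, match="single tester"):
        gca_sca_decompose(df)


def test_permuting_testers_destroys_tester_gca():
    df = _ncii_values(60, s2_gr=1.0, s2_gt=2.0, s2_sca=0.2, s2_e=0.3, seed=17)
    base = gca_sca_decompose(df)
    rng = np.random.default_rng(18)
    perm = df.copy()
    for (ril, env), idx in perm.groupby(["ril", "environment"]).groups.items():
        perm.loc[idx, "tester"] = rng.permutation(perm.loc[idx, "tester"].to_numpy())
    shuffled = gca_sca_decompose(perm)
    assert shuffled.variances["gca_tester"] < 0.25 * base.variances["gca_tester"]


# ---------------------------------------------------------------------------
# correlations and path analysis

def test_single_predictor_path_equals_correlation():
    rng = np.random.default_rng(19)
    x = rng.normal(size=200)
    y = 0.6 * x + rng.normal(size=200)
    df = pd.DataFrame({"X": x, "Y": y})
    res = correlations_and_path(df, "Y")
    assert res.path_coefficients["X"] == pytest.approx(res.correlations.loc["X", "Y"])


def test_orthogonal_predictors_paths_equal_correlations():
    rng = np.random.default_rng(20)
    n = 4000
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 0.5 * x1 - 0.3 * x2 + rng.normal(size=n)
    df = pd.DataFrame({"A": x1, "B": x2, "Y": y})
    res = correlations_and_path(df, "Y")
    assert res.path_coefficients["A"] == pytest.approx(res.correlations.loc["A", "Y"], abs=0.05)
    assert res.path_coefficients["B"] == pytest.approx(res.correlations.loc["B", "Y"], abs=0.05)


def test_path_matches_normal_equations():
    rng = np.random.default_rng(21)
    n = 150
    X = rng.normal(size=(n, 4)) @ (np.eye(4) + 0.4 * np.ones((4, 4)))
    y = X @ np.array([0.5, -0.2, 0.0, 0.8]) + rng.normal(size=n)
    df = pd.DataFrame(X, columns=list("ABCD"))
    df["Y"] = y
    res = correlations_and_path(df, "Y")
    # independent oracle: normal equations R_xx^{-1} r_xy on standardized data
    R = df.corr()
    beta = np.linalg.solve(R.loc[list("ABCD"), list("ABCD")],
                           R.loc[list("ABCD"), "Y"])
    np.testing.assert_allclose(res.path_coefficients.to_numpy(), beta, atol=1e-10)
    # correlation matrix contract
    np.testing.assert_allclose(res.correlations, res.correlations.T)
    np.testing.assert_allclose(np.diag(res.correlations), 1.0)


def test_collinear_predictors_flagged():
    rng = np.random.default_rng(22)
    x = rng.normal(size=50)
    df = pd.DataFrame({"A": x, "B": x * 2.0 + 1e-9 * rng.normal(size=50),
                       "Y": x + rng.normal(size=50)})
    with pytest.warns(UserWarning, match="collinear"):
        res = correlations_and_path(df, "Y")
    assert res.unstable


def test_path_display_threshold():
    rng = np.random.default_rng(23)
    n = 500
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 0.8 * x1 + 0.01 * x2 + rng.normal(size=n)
    df = pd.DataFrame({"big": x1, "small": x2, "Y": y})
    res = correlations_and_path(df, "Y")
    shown = res.display()
    assert "big" in shown.index and "small" not in shown.index
    assert "small" in res.path_coefficients.index  # stored, only hidden
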
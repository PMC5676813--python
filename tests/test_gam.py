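"""Penalized-spline mixed models: basis, REML fit, term tests, curves."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cortmorph.gam import (
    GAMConfig,
    fit_gam_mixed,
    fitted_age_curves,
    fixed_effect_test,
    model_r2,
    smooth_term_test,
    spline_basis,
    trajectory_table,
)

NO_FAMILY = GAMConfig(family_column=None)


def _cohort(rng, n=300, y=None, families=None):
    df = pd.DataFrame(
        dict(
            age=rng.uniform(8, 29, n),
            sex=rng.choice(["male", "female"], n),
            scanner=rng.choice(["site_a", "site_b"], n),
        )
    )
    df["family"] = families if families is not None else [f"f{i}" for i in range(n)]
    df["y"] = y(df) if callable(y) else (y if y is not None else rng.normal(0, 1, n))
    return df


def test_basis_partition_of_unity_and_penalty_rank():
    rng = np.random.default_rng(0)
    ages = rng.uniform(8, 29, 200)
    basis = spline_basis(ages, k=10)
    B = basis.raw(ages)
    assert np.abs(B.sum(axis=1) - 1.0).max() <= 1e-12
    evals = np.linalg.eigvalsh(basis.penalty)
    assert (evals < 1e-10).sum() == 2  # rank k-2

    # coefficients linear in index are annihilated by the 2nd-difference penalty
    coef = np.linspace(-1, 1, 10)
    assert coef @ basis.penalty @ coef <= 1e-12

    # the unpenalized smooth column is an exact affine function of age
    lin = basis.linear_column(ages)
    fitresid = lin - np.polyval(np.polyfit(ages, lin, 1), ages)
    assert np.abs(fitresid).max() <= 1e-9


def test_basis_needs_enough_distinct_ages():
    with pytest.raises(ValueError, match="k=10"):
        spline_basis(np.array([1.0, 2.0, 3.0] * 10), k=10)


def test_infinite_smoothing_reproduces_ols():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    df = _cohort(rng, 250, y=lambda d: 2 + 0.1 * d.age + rng.normal(0, 1, len(d)))
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY, lambda_smooth=np.inf)
    X = sm.add_constant(
        pd.DataFrame(
            dict(
                sex=(df.sex == "male").astype(float),
                scanner=(df.scanner == "site_b").astype(float),
                age=df.age,
            )
        )
    )
    ols = sm.OLS(df.y, X).fit()
    assert np.abs(fit.fitted - ols.fittedvalues.to_numpy()).max() <= 1e-8
    assert fit.smooth_edf == pytest.approx(1.0, abs=1e-9)


def test_linear_truth_recovered_with_edf_near_one():
    rng = np.random.default_rng(2)
    df = _cohort(rng, 400, y=lambda d: 3 - 0.1 * d.age + rng.normal(0, 0.5, len(d)))
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY)
    assert fit.smooth_edf <= 1.3
    curves = fitted_age_curves(fit, np.array([12.0, 22.0]))
    male = curves[curves.sex == "male"]
    slope = (male.fit.iloc[1] - male.fit.iloc[0]) / 10.0
    se = math.sqrt(male.se.iloc[0] ** 2 + male.se.iloc[1] ** 2) / 10.0
    assert abs(slope - (-0.1)) <= 2 * se


def test_family_variance_components_recovered():
    rng = np.random.default_rng(3)
    nf, size = 60, 3
    fams = [f"f{i}" for i in range(nf) for _ in range(size)]
    df = _cohort(rng, nf * size, families=fams)
    b = rng.normal(0, 1.0, nf)
    df["y"] = 1.0 + 0.02 * df.age + np.repeat(b, size) + rng.normal(0, 0.5, len(df))
    fit = fit_gam_mixed(df, "y")
    assert math.sqrt(fit.sigma2_family) == pytest.approx(1.0, rel=0.3)
    assert math.sqrt(fit.sigma2_resid) == pytest.approx(0.5, rel=0.3)


def test_smooth_f_equals_classical_f_at_infinite_lambda():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    df = _cohort(rng, 200)
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY, lambda_smooth=np.inf)
    test = smooth_term_test(fit)
    X = sm.add_constant(
        pd.DataFrame(
            dict(
                sex=(df.sex == "male").astype(float),
                scanner=(df.scanner == "site_b").astype(float),
                age=df.age,
            )
        )
    )
    ols = sm.OLS(df.y, X).fit()
    assert test.statistic == pytest.approx(ols.tvalues["age"] ** 2, rel=1e-6)
    assert test.p == pytest.approx(ols.pvalues["age"], rel=1e-6)


def test_sex_effect_power_at_study_scale():
    rng = np.random.default_rng(5)
    hits = 0
    reps = 60
    for _ in range(reps):
        df = _cohort(rng, 218)
        df["y"] = 0.8 * (df.sex == "male") + rng.normal(0, 1, len(df))
        fit = fit_gam_mixed(df, "y", config=NO_FAMILY)
        hits += fixed_effect_test(fit, "sex").p < 0.002
    assert hits / reps >= 0.95


def test_fixed_effect_null_calibrated():
    rng = np.random.default_rng(6)
    hits = 0
    reps = 200
    for _ in range(reps):
        df = _cohort(rng, 150)
        hits += fixed_effect_test(fit_gam_mixed(df, "y", config=NO_FAMILY), "sex").p < 0.05
    assert 0.02 <= hits / reps <= 0.09


def test_collinear_fixed_design_rejected():
    rng = np.random.default_rng(7)
    df = _cohort(rng, 100)
    df["scanner"] = df["sex"].map({"male": "site_a", "female": "site_b"})
    with pytest.raises(ValueError, match="collinear"):
        fit_gam_mixed(df, "y", config=NO_FAMILY)


def test_missing_term_raises():
    rng = np.random.default_rng(8)
    fit = fit_gam_mixed(_cohort(rng, 120), "y", config=NO_FAMILY)
    with pytest.raises(KeyError, match="iq"):
        fixed_effect_test(fit, "iq")


def test_r2_extremes_and_oracle():
    rng = np.random.default_rng(9)
    df = _cohort(rng, 150, y=lambda d: 1.0 + 0.2 * d.age)
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY)
    assert model_r2(fit) == pytest.approx(100.0, abs=1e-6)
    recomputed = 100 * np.corrcoef(fit.y, fit.fitted)[0, 1] ** 2
    assert model_r2(fit) == pytest.approx(recomputed, abs=1e-12)

    noise = fit_gam_mixed(_cohort(rng, 500), "y", config=NO_FAMILY)
    assert model_r2(noise) < 10.0


def test_edf_monotone_in_lambda():
    rng = np.random.default_rng(10)
    df = _cohort(rng, 250, y=lambda d: np.sin(d.age / 2) + rng.normal(0, 0.3, len(d)))
    edfs = [
        fit_gam_mixed(df, "y", config=NO_FAMILY, lambda_smooth=lam).smooth_edf
        for lam in (1e-4, 1e-2, 1.0, 1e2, 1e4)
    ]
    assert all(a > b for a, b in zip(edfs, edfs[1:]))


def test_duplicated_families_shrink_evidence():
    """Cloning every subject into a 2-member family (same family effect,
    fresh residual noise) must not double the apparent evidence: the
    family random intercept absorbs the shared component, giving a
    smaller age F than a model that pretends all rows are independent."""
    rng = np.random.default_rng(11)
    n = 150
    df = _cohort(rng, n)
    shared = 0.05 * df.age.to_numpy() + rng.normal(0, 1, n)  # subject-level signal
    twin = df.copy()
    df["y"] = shared + rng.normal(0, 0.3, n)
    twin["y"] = shared + rng.normal(0, 0.3, n)
    doubled = pd.concat([df, twin], ignore_index=True)
    doubled["family"] = [f"f{i}" for i in range(n)] * 2
    with_fam = fit_gam_mixed(doubled, "y")
    without = fit_gam_mixed(doubled, "y", config=NO_FAMILY)
    assert with_fam.sigma2_family > 0
    assert smooth_term_test(with_fam).statistic < smooth_term_test(without).statistic


def test_parallel_curves_without_interaction():
    rng = np.random.default_rng(12)
    df = _cohort(rng, 300, y=lambda d: 0.6 * (d.sex == "male") + 0.05 * d.age
                 + rng.normal(0, 0.4, len(d)))
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY)
    grid = np.linspace(10, 28, 12)
    curves = fitted_age_curves(fit, grid)
    male = curves[curves.sex == "male"].fit.to_numpy()
    female = curves[curves.sex == "female"].fit.to_numpy()
    diffs = male - female
    assert np.abs(diffs - diffs[0]).max() <= 1e-9


def test_interaction_recovers_differing_slopes():
    rng = np.random.default_rng(13)
    n = 500
    df = _cohort(rng, n)
    is_male = (df.sex == "male").to_numpy()
    df["y"] = 0.10 * df.age * is_male + 0.02 * df.age * ~is_male + rng.normal(0, 0.3, n)
    cfg = GAMConfig(family_column=None, age_by_sex=True)
    fit = fit_gam_mixed(df, "y", config=cfg)
    curves = fitted_age_curves(fit, np.array([12.0, 26.0]))
    male = curves[curves.sex == "male"]
    female = curves[curves.sex == "female"]
    slope_m = (male.fit.iloc[1] - male.fit.iloc[0]) / 14.0
    slope_f = (female.fit.iloc[1] - female.fit.iloc[0]) / 14.0
    diff = slope_m - slope_f
    # pointwise SEs ignore the endpoint covariance, so a nominal 2-SE
    # bound is not exact; assert recovery within a quarter of the effect
    assert abs(diff - 0.08) <= 0.02
    assert slope_m > slope_f  # curves are genuinely non-parallel


def test_se_smaller_where_data_dense():
    rng = np.random.default_rng(14)
    ages = np.concatenate([rng.uniform(14, 20, 360), rng.uniform(8, 29, 40)])
    df = pd.DataFrame(dict(age=ages, sex=rng.choice(["male", "female"], 400),
                           scanner=rng.choice(["site_a", "site_b"], 400)))
    df["y"] = np.sin(df.age / 3) + rng.normal(0, 0.4, 400)
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY)
    curves = fitted_age_curves(fit, np.array([8.5, 17.0, 28.5]))
    male = curves[curves.sex == "male"]
    assert male.se.iloc[1] < male.se.iloc[0]
    assert male.se.iloc[1] < male.se.iloc[2]


def test_extrapolation_flagged():
    rng = np.random.default_rng(15)
    fit = fit_gam_mixed(_cohort(rng, 150), "y", config=NO_FAMILY)
    curves = fitted_age_curves(fit, np.array([5.0, 15.0, 40.0]))
    male = curves[curves.sex == "male"]
    assert bool(male.extrapolated.iloc[0]) and bool(male.extrapolated.iloc[2])
    assert not male.extrapolated.iloc[1]


def test_trajectory_grid_shape_and_flags(cohort_table):
    table, _ = cohort_table
    grid = trajectory_table(table)
    assert len(grid) == 24  # 4 indices x 6 regions
    assert grid.attrs["bonferroni_cutoff"] == pytest.approx(0.002)
    # CT declines with age by construction -> age significant everywhere
    ct = grid[grid["index"] == "ct_mean"]
    assert ct.age_significant.all()
    # SA has no age trend by construction
    sa = grid[grid["index"] == "sa"]
    assert (~sa.age_significant).all()


def test_fit_agrees_with_mgcv_reference():
    """Independent oracle: R mgcv (P-spline, REML) on a shared dataset."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; mgcv cross-check cannot run")
    rng = np.random.default_rng(16)
    n = 250
    df = _cohort(rng, n, y=lambda d: 2.5 + 1.2 * np.exp(-0.15 * (d.age - 8))
                 + 0.3 * (d.sex == "male") + rng.normal(0, 0.25, len(d)))
    fit = fit_gam_mixed(df, "y", config=NO_FAMILY)
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        data_csv = os.path.join(td, "d.csv")
        out_csv = os.path.join(td, "out.csv")
        df.to_csv(data_csv, index=False)
        r_code = (
            f'd <- read.csv("{data_csv}"); library(mgcv); '
            f'm <- gam(y ~ s(age, bs="ps", k=10, m=c(2,2)) + sex + scanner, '
            f'data=d, method="REML"); '
            f'write.csv(data.frame(fitted=fitted(m), edf=sum(m.edf <- m$edf[2:9]) + 1), '
            f'"{out_csv}", row.names=FALSE)'
        )
        proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr[-500:]
        ref = pd.read_csv(out_csv)
    rmse = float(np.sqrt(np.mean((fit.fitted - ref.fitted.to_numpy()) ** 2)))
    assert rmse <= 0.02 * df.y.std()
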
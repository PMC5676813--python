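"""Penalized-spline mixed-effect growth models.

Each regional index is modeled as a smooth function of age plus linear
fixed effects (sex, scanner, optionally total surface area and IQ) and a
family random intercept for sibling clustering:

    y_ij = f(age_ij) + x_ij' beta + b_{family(ij)} + e_ij,
    b ~ N(0, sigma_f^2),  e ~ N(0, sigma_e^2).

The smooth is a cubic B-spline with a second-order difference penalty,
recast in mixed-model form: the penalty null space contributes an
unpenalized linear-age fixed column, and the penalized "wiggle"
directions become a random-effect block with variance sigma_e^2/lambda.
All variance components (smoothing parameter included) are estimated by
restricted maximum likelihood in one pass, and the smooth's flexibility
is summarized by its effective degrees of freedom (edf, between 1 =
linear and k-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "GAMConfig",
    "GAMFit",
    "TermTest",
    "spline_basis",
    "fit_gam_mixed",
    "smooth_term_test",
    "fixed_effect_test",
    "model_r2",
    "fitted_age_curves",
    "trajectory_table",
]


@dataclass
class GAMConfig:
    """Model settings for one penalized-spline mixed fit."""

    k: int = 10  # basis dimension of the age smooth
    degree: int = 3  # cubic
    penalty_order: int = 2  # second differences
    covariates: tuple = ("sex", "scanner")
    include_total_sa: bool = False
    age_by_sex: bool = False
    include_iq: bool = False
    family_column: Optional[str] = "family"
    reml_tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("basis dimension k must be >= 4")
        if self.penalty_order >= self.k:
            raise ValueError("penalty order must be below k")


@dataclass
class SplineBasis:
    """B-spline design with its difference penalty and the mixed-model
    reparametrization (linear null-space column + iid wiggle block)."""

    knots: np.ndarray
    degree: int
    k: int
    penalty: np.ndarray  # k x k, PSD, rank k - penalty_order
    null_transform: np.ndarray  # k x 1: non-constant null direction
    wiggle_transform: np.ndarray  # k x (k - penalty_order)
    x_center: float

    def raw(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def linear_column(self, x: np.ndarray) -> np.ndarray:
        return (self.raw(x) @ self.null_transform).ravel() - self.x_center

    def wiggle_columns(self, x: np.ndarray) -> np.ndarray:
        return self.raw(x) @ self.wiggle_transform


def spline_basis(
    ages: np.ndarray, k: int = 10, degree: int = 3, penalty_order: int = 2
) -> SplineBasis:
    """Construct the age-smooth basis: uniform unclamped B-splines over
    the age range (rows sum to 1 over the data) with the
    positive-semidefinite ``penalty_order``-difference penalty of rank
    k - penalty_order.

    Uniform knot spacing makes the Greville abscissae equally spaced, so
    coefficient vectors in the difference-penalty null space map exactly
    onto constant and linear functions of age — the property that lets
    the smooth split cleanly into an unpenalized linear term plus
    penalized wiggle, and makes the infinite-smoothing limit reproduce a
    plain linear model.
    """
    ages = np.asarray(ages, dtype=float)
    if len(np.unique(ages)) < k:
        raise ValueError(
            f"need at least k={k} distinct ages (got {len(np.unique(ages))}); "
            "reduce k"
        )
    lo, hi = float(ages.min()), float(ages.max())
    nseg = k - degree
    h = (hi - lo) / nseg
    knots = lo + h * np.arange(-degree, nseg + degree + 1)

    D = np.diff(np.eye(k), n=penalty_order, axis=0)
    S = D.T @ D

    # split coefficient space into penalty null space and range
    evals, evecs = np.linalg.eigh(S)
    null = evecs[:, :penalty_order]
    # rotate the null basis so one direction is the constant function
    # (B-spline rows sum to 1, and the all-ones coefficient vector is in
    # the null space of the difference penalty)
    ones = np.ones(k) / math.sqrt(k)
    coef = null.T @ ones
    n1 = null @ coef
    n1 /= np.linalg.norm(n1)
    resid = null - np.outer(n1, n1 @ null)
    # remaining null direction(s), orthogonal to the constant
    q, r = np.linalg.qr(resid)
    keep = np.abs(np.diag(r)) > 1e-10
    n2 = q[:, keep][:, :1]
    wiggle = evecs[:, penalty_order:] / np.sqrt(evals[penalty_order:])

    basis = SplineBasis(
        knots=knots,
        degree=degree,
        k=k,
        penalty=S,
        null_transform=n2,
        wiggle_transform=wiggle,
        x_center=0.0,
    )
    basis.x_center = float((basis.raw(ages) @ n2).mean())
    return basis


@dataclass
class TermTest:
    term: str
    statistic: float
    kind: str  # "F" or "t"
    df1: float
    df2: float
    p: float


@dataclass
class GAMFit:
    """Fitted penalized-spline mixed model."""

    config: GAMConfig
    basis: SplineBasis
    coefficients: np.ndarray
    cov: np.ndarray  # Bayesian covariance sigma_e^2 (X'X+P)^-1
    column_names: list
    blocks: dict  # name -> column index array
    lambda_smooth: float
    lambda_family: float
    sigma2_resid: float
    sigma2_smooth: float
    sigma2_family: float
    edf: np.ndarray  # per-column effective degrees of freedom
    fitted: np.ndarray
    residuals: np.ndarray
    y: np.ndarray
    n: int
    converged: bool
    reml: float
    family_levels: Optional[list] = None
    covariate_means: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def smooth_edf(self) -> float:
        """edf of the age smooth (linear column + wiggle block)."""
        idx = np.concatenate([self.blocks["age_linear"], self.blocks.get("wiggle", [])])
        return float(self.edf[np.asarray(idx, dtype=int)].sum())

    @property
    def total_edf(self) -> float:
        return float(self.edf.sum())

    @property
    def df_residual(self) -> float:
        return self.n - self.total_edf


def _encode_covariates(df: pd.DataFrame, covariates: Sequence[str]):
    cols, names, means = [], [], {}
    for c in covariates:
        col = df[c]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {c!r} is constant")
            for lv in levels[1:]:
                v = (col == lv).to_numpy(dtype=float)
                cols.append(v)
                names.append(f"{c}[{lv}]")
                means[f"{c}[{lv}]"] = float(v.mean())
        else:
            v = col.to_numpy(dtype=float)
            vc = v - v.mean()
            cols.append(vc)
            names.append(c)
            means[c] = 0.0  # centered
    return cols, names, means


def _reml_neg2(log_lambdas, XtX, Xty, yty, n, Mp, block_slices):
    """-2 restricted log-likelihood with sigma_e^2 profiled out.

    ``block_slices``: list of (slice, size) for each penalized iid block,
    in the order of ``log_lambdas``.
    """
    p = XtX.shape[0]
    P = np.zeros(p)
    pen_logdet = 0.0
    for (sl, size), ll in zip(block_slices, log_lambdas):
        lam = math.exp(ll)
        P[sl] = lam
        pen_logdet += size * ll
    A = XtX + np.diag(P)
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return 1e30, None, None
    beta = sla.cho_solve((L, True), Xty)
    Dp = yty - 2 * beta @ Xty + beta @ (XtX @ beta) + np.sum(P * beta * beta)
    Dp = max(Dp, 1e-300)
    sigma2 = Dp / (n - Mp)
    logdetA = 2.0 * np.sum(np.log(np.diag(L)))
    neg2 = (n - Mp) * (math.log(2 * math.pi * sigma2) + 1.0) + logdetA - pen_logdet
    return neg2, beta, sigma2


def fit_gam_mixed(
    data: pd.DataFrame,
    response: str,
    config: Optional[GAMConfig] = None,
    age_column: str = "age",
    lambda_smooth: Optional[float] = None,
) -> GAMFit:
    """Fit the penalized-spline mixed model for one region and index.

    ``data`` holds one row per subject with the response, age, categorical
    covariates, and the family identifier.  Smoothing and family variance
    are selected by REML unless ``lambda_smooth`` pins the smoothing
    parameter (``numpy.inf`` collapses the smooth to an exact linear age
    term, reproducing OLS when the family variance is also absent).
    Complete-case analysis.
    """
    config = config or GAMConfig()
    notes = []
    cols_needed = [response, age_column] + list(config.covariates)
    if config.include_total_sa:
        cols_needed.append("total_sa")
    if config.include_iq:
        cols_needed.append("iq")
    fam_col = config.family_column
    if fam_col is not None and fam_col in data.columns:
        cols_needed.append(fam_col)
    else:
        fam_col = None
    df = data.dropna(subset=[c for c in cols_needed if c in data.columns]).reset_index(drop=True)
    n = len(df)
    if n < config.k + len(config.covariates) + 3:
        raise ValueError(f"too few complete cases ({n}) for the model")

    y = df[response].to_numpy(dtype=float)
    ages = df[age_column].to_numpy(dtype=float)
    basis = spline_basis(ages, k=config.k, degree=config.degree,
                         penalty_order=config.penalty_order)

    covariates = list(config.covariates)
    extra = []
    if config.include_total_sa:
        extra.append("total_sa")
    if config.include_iq:
        extra.append("iq")
    cov_cols, cov_names, cov_means = _encode_covariates(df, covariates + extra)

    columns = [np.ones(n)]
    names = ["intercept"]
    blocks: dict = {"fixed": [0]}
    for v, nm in zip(cov_cols, cov_names):
        columns.append(v)
        names.append(nm)
        blocks["fixed"].append(len(columns) - 1)

    sex_indicator = None
    if config.age_by_sex:
        sex_names = [nm for nm in cov_names if nm.startswith("sex[")]
        if not sex_names:
            raise ValueError("age_by_sex requires a two-level sex covariate")
        sex_indicator = cov_cols[cov_names.index(sex_names[0])]

    x_lin = basis.linear_column(ages)
    blocks["age_linear"] = [len(columns)]
    columns.append(x_lin)
    names.append("age_linear")
    if config.age_by_sex:
        blocks["age_linear"].append(len(columns))
        columns.append(x_lin * sex_indicator)
        names.append("age_linear:sex")

    use_wiggle = not (lambda_smooth is not None and math.isinf(lambda_smooth))
    wiggle_slices = []
    if use_wiggle:
        W = basis.wiggle_columns(ages)
        if config.age_by_sex:
            W = np.hstack([W, W * sex_indicator[:, None]])
        start = len(columns)
        for j in range(W.shape[1]):
            columns.append(W[:, j])
            names.append(f"wiggle{j}")
        blocks["wiggle"] = list(range(start, start + W.shape[1]))
        wiggle_slices.append((slice(start, start + W.shape[1]), W.shape[1]))

    family_levels = None
    fam_slice = None
    if fam_col is not None:
        fam = df[fam_col].astype(str)
        family_levels = sorted(fam.unique())
        counts = fam.value_counts()
        if (counts >= 2).sum() < 2:
            notes.append(
                "family random intercept unidentified (<2 multi-member families); "
                "variance pinned to 0"
            )
            warnings.warn(notes[-1])
            family_levels = None
        else:
            Z = (fam.to_numpy()[:, None] == np.array(family_levels)[None, :]).astype(float)
            start = len(columns)
            for j in range(Z.shape[1]):
                columns.append(Z[:, j])
                names.append(f"family[{family_levels[j]}]")
            blocks["family"] = list(range(start, start + Z.shape[1]))
            fam_slice = (slice(start, start + Z.shape[1]), Z.shape[1])

    X = np.column_stack(columns)
    p = X.shape[1]
    Mp = len(blocks["fixed"]) + len(blocks["age_linear"])
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    if np.linalg.matrix_rank(XtX[:Mp, :Mp]) < Mp:
        const = [names[i] for i in range(Mp) if np.std(X[:, i]) == 0 and i > 0]
        raise ValueError(f"collinear fixed-effect design (suspect columns: {const or 'unknown'})")

    pen_blocks = []
    if use_wiggle:
        pen_blocks.append(("smooth", wiggle_slices[0]))
    if fam_slice is not None:
        pen_blocks.append(("family", fam_slice))

    fixed_ll = {}
    if lambda_smooth is not None and use_wiggle:
        fixed_ll["smooth"] = math.log(lambda_smooth)

    free = [nm for nm, _ in pen_blocks if nm not in fixed_ll]
    converged = True
    if free or fixed_ll:
        def objective(theta):
            lls = []
            it = iter(theta)
            for nm, _ in pen_blocks:
                lls.append(fixed_ll[nm] if nm in fixed_ll else next(it))
            return _reml_neg2(lls, XtX, Xty, yty, n, Mp,
                              [bs for _, bs in pen_blocks])[0]

        if free:
            best = None
            for x0 in ([0.0] * len(free), [5.0] * len(free), [-5.0] * len(free)):
                res = optimize.minimize(
                    objective, x0, method="Nelder-Mead",
                    options=dict(xatol=1e-6, fatol=config.reml_tol,
                                 maxiter=200 * config.max_iter),
                )
                if best is None or res.fun < best.fun:
                    best = res
            converged = bool(best.success) or best.fun < 1e29
            if not converged:
                raise RuntimeError(
                    f"REML optimization failed to converge (last value {best.fun:.3g})"
                )
            theta = list(best.x)
        else:
            theta = []
        lls = []
        it = iter(theta)
        for nm, _ in pen_blocks:
            lls.append(fixed_ll[nm] if nm in fixed_ll else next(it))
        neg2, beta, sigma2 = _reml_neg2(lls, XtX, Xty, yty, n, Mp,
                                        [bs for _, bs in pen_blocks])
    else:
        lls = []
        neg2, beta, sigma2 = _reml_neg2([], XtX, Xty, yty, n, Mp, [])

    lam = dict(zip([nm for nm, _ in pen_blocks], [math.exp(v) for v in lls]))
    lam_s = lam.get("smooth", math.inf)
    lam_f = lam.get("family", math.inf)

    P = np.zeros(p)
    for (nm, (sl, _)), ll in zip(pen_blocks, lls):
        P[sl] = math.exp(ll)
    A = XtX + np.diag(P)
    Ainv = np.linalg.inv(A)
    F = Ainv @ XtX
    edf = np.diag(F).copy()
    fitted = X @ beta
    resid = y - fitted
    cov = sigma2 * Ainv

    return GAMFit(
        config=config,
        basis=basis,
        coefficients=beta,
        cov=cov,
        column_names=names,
        blocks={k2: np.array(v, dtype=int) for k2, v in blocks.items()},
        lambda_smooth=lam_s,
        lambda_family=lam_f,
        sigma2_resid=float(sigma2),
        sigma2_smooth=float(sigma2 / lam_s) if np.isfinite(lam_s) else 0.0,
        sigma2_family=float(sigma2 / lam_f) if np.isfinite(lam_f) else 0.0,
        edf=edf,
        fitted=fitted,
        residuals=resid,
        y=y,
        n=n,
        converged=converged,
        reml=-0.5 * neg2,
        family_levels=family_levels,
        covariate_means=cov_means,
        warnings=notes,
    )


def smooth_term_test(fit: GAMFit) -> TermTest:
    """Wald-type F test of the whole age smooth (linear + wiggle block).

    The numerator uses the pseudo-inverse of the smooth block's Bayesian
    covariance at rank ceil(edf); the denominator dof is the residual
    dof n - total edf.  The reference distribution is approximate; its
    calibration is established by simulation rather than exact theory.
    """
    idx = np.concatenate([fit.blocks["age_linear"], fit.blocks.get("wiggle", [])]).astype(int)
    beta = fit.coefficients[idx]
    V = fit.cov[np.ix_(idx, idx)]
    edf_s = fit.smooth_edf
    if edf_s < 1.0:
        warnings.warn("smooth edf below 1; clamped for the reference dof")
        edf_s = 1.0
    r = min(int(math.ceil(edf_s)), len(idx))
    evals, evecs = np.linalg.eigh(V)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order][:r], evecs[:, order][:, :r]
    proj = evecs.T @ beta
    stat = float(proj @ (proj / evals)) / r
    df2 = fit.df_residual
    p = float(stats.f.sf(stat, r, df2))
    return TermTest(term="s(age)", statistic=stat, kind="F", df1=r, df2=df2, p=p)


def fixed_effect_test(fit: GAMFit, term: str) -> TermTest:
    """t test of a linear fixed effect (e.g. ``sex[male]``)."""
    matches = [i for i, nm in enumerate(fit.column_names) if nm == term or nm.startswith(f"{term}[")]
    matches = [i for i in matches if i in set(fit.blocks["fixed"]) | set(fit.blocks["age_linear"])]
    if not matches:
        raise KeyError(f"term {term!r} not in model; columns: {fit.column_names}")
    i = matches[0]
    se = math.sqrt(fit.cov[i, i])
    t = fit.coefficients[i] / se
    df = fit.df_residual
    p = float(2 * stats.t.sf(abs(t), df))
    return TermTest(term=fit.column_names[i], statistic=float(t), kind="t", df1=1, df2=df, p=p)


def model_r2(fit: GAMFit) -> float:
    """Full-model R^2 in percent: squared correlation of observed and
    fitted values (fixed effects plus predicted family intercepts)."""
    if np.std(fit.fitted) == 0 or np.std(fit.y) == 0:
        return 0.0
    r = np.corrcoef(fit.y, fit.fitted)[0, 1]
    return float(100.0 * r * r)


def fitted_age_curves(
    fit: GAMFit,
    age_grid: Optional[np.ndarray] = None,
    sex_levels: Sequence[str] = ("male", "female"),
) -> pd.DataFrame:
    """Predicted mean and pointwise SE per sex over an age grid.

    Predictions are at the reference scanner with numeric covariates at
    their (centered) means and family effect zero.  Ages outside the
    fitted range are flagged as extrapolation.
    """
    lo = fit.basis.knots[fit.basis.degree]
    hi = fit.basis.knots[-fit.basis.degree - 1]
    if age_grid is None:
        age_grid = np.linspace(lo, hi, 60)
    age_grid = np.asarray(age_grid, dtype=float)
    extrapolated = (age_grid < lo) | (age_grid > hi)

    sex_cols = [nm for nm in fit.column_names if nm.startswith("sex[")]
    rows = []
    for sex in sex_levels:
        Xp = np.zeros((len(age_grid), len(fit.column_names)))
        Xp[:, fit.column_names.index("intercept")] = 1.0
        for nm in sex_cols:
            level = nm[nm.index("[") + 1 : -1]
            if level == sex:
                Xp[:, fit.column_names.index(nm)] = 1.0
        lin = fit.basis.linear_column(age_grid)
        Xp[:, fit.blocks["age_linear"][0]] = lin
        if "wiggle" in fit.blocks:
            W = fit.basis.wiggle_columns(age_grid)
            widx = fit.blocks["wiggle"]
            if fit.config.age_by_sex:
                is_male_level = 1.0 if sex_cols and f"sex[{sex}]" in sex_cols else 0.0
                half = W.shape[1]
                Xp[:, widx[:half]] = W
                Xp[:, widx[half:]] = W * is_male_level
                if len(fit.blocks["age_linear"]) > 1:
                    Xp[:, fit.blocks["age_linear"][1]] = lin * is_male_level
            else:
                Xp[:, widx] = W
        pred = Xp @ fit.coefficients
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xp, fit.cov, Xp))
        for a, f_, s_, ex in zip(age_grid, pred, se, extrapolated):
            rows.append(dict(age=a, sex=sex, fit=f_, se=s_, extrapolated=bool(ex)))
    return pd.DataFrame(rows)


def trajectory_table(
    table: pd.DataFrame,
    indices: Sequence[str] = ("ic_skew", "ct_mean", "lgi_mean", "sa"),
    regions: Optional[Sequence[str]] = None,
    config: Optional[GAMConfig] = None,
    alpha: float = 0.05,
    hemisphere: str = "mean",
) -> pd.DataFrame:
    """Per region x index: Age F, Age p, Sex t, Sex p, full-model R^2 (%).

    Significance is flagged at the Bonferroni threshold for the grid size
    (regions x indices tests), truncated to one significant figure.
    Models of thickness, gyrification and curvature conventionally add
    total SA as a covariate via ``config.include_total_sa``.
    """
    from .associations import bonferroni_cutoff

    config = config or GAMConfig()
    if regions is None:
        regions = list(dict.fromkeys(table["region"]))
    rows = []
    for index in indices:
        for region in regions:
            sub = table[(table["region"] == region) & (table["hemisphere"] == hemisphere)]
            fit = fit_gam_mixed(sub, index, config=config)
            age_test = smooth_term_test(fit)
            sex_test = fixed_effect_test(fit, "sex")
            rows.append(
                dict(
                    index=index,
                    region=region,
                    age_F=age_test.statistic,
                    age_p=age_test.p,
                    sex_t=sex_test.statistic,
                    sex_p=sex_test.p,
                    r2_percent=model_r2(fit),
                    edf=fit.smooth_edf,
                    n=fit.n,
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        cutoff, exact = bonferroni_cutoff(alpha, len(out))
        out["age_significant"] = out["age_p"] < cutoff
        out["sex_significant"] = out["sex_p"] < cutoff
        out.attrs["bonferroni_cutoff"] = cutoff
        out.attrs["bonferroni_exact"] = exact
        out.attrs["n_tests"] = len(out)
    return out
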
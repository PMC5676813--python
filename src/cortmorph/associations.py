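"""Inter-index associations: covariate-adjusted linear models, partial
correlations, and Bonferroni control.

For each region and each unordered pair of indices the association is
assessed two ways, mirroring common practice in regional morphometry:
an ordinary least-squares model of index A on index B adjusting for age
and sex supplies the significance test, while a Pearson partial
correlation (residual-on-residual, adjusting for age by default)
supplies the effect-size estimate shown in the results grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regions import ANALYSIS_REGIONS, INDEX_COLUMNS

__all__ = [
    "AssociationResult",
    "adjusted_association",
    "partial_correlation",
    "bonferroni_cutoff",
    "association_table",
    "render_association_table",
    "STAR_TIERS",
]

# star tiers of the rendered grid (threshold, marker), most stringent last
STAR_TIERS = ((1e-3, "*"), (3e-4, "**"), (3e-5, "***"))

DEFAULT_MODEL_COVARIATES = ("age", "sex")
DEFAULT_PARTIAL_COVARIATES = ("age",)


@dataclass
class AssociationResult:
    region: str
    index_a: str
    index_b: str
    coefficient: float
    t: float
    p: float
    partial_r: float
    n: int


def _design(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns; sex and scanner become indicator columns
    (reference levels: female, site_a — alphabetical first)."""
    out = {}
    for c in columns:
        col = table[c]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {c!r} is constant")
            for lv in levels[1:]:
                out[f"{c}[{lv}]"] = (col == lv).astype(float)
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out, index=table.index)


def _region_rows(table: pd.DataFrame, region: str, hemisphere: str = "mean") -> pd.DataFrame:
    sub = table[(table["region"] == region) & (table["hemisphere"] == hemisphere)]
    if sub.empty:
        raise ValueError(f"no rows for region {region!r} (hemisphere {hemisphere!r})")
    return sub


def adjusted_association(
    table: pd.DataFrame,
    region: str,
    index_a: str,
    index_b: str,
    covariates: Sequence[str] = DEFAULT_MODEL_COVARIATES,
    hemisphere: str = "mean",
) -> AssociationResult:
    """OLS of ``index_a`` on ``index_b`` plus covariates within one region.

    Reports index_b's coefficient with its t statistic and two-sided p,
    and attaches the partial correlation (age-adjusted by default) as the
    effect size.  Complete-case analysis; collinear designs raise.
    """
    sub = _region_rows(table, region, hemisphere)
    cols = [index_a, index_b] + [c for c in covariates]
    sub = sub.dropna(subset=[c for c in cols if c in sub.columns])
    X = pd.concat([sub[[index_b]].astype(float), _design(sub, covariates)], axis=1)
    n = len(sub)
    if n < X.shape[1] + 2:
        raise ValueError(f"too few complete cases ({n}) for {X.shape[1] + 1} parameters")
    for c in X.columns:
        if np.std(X[c].to_numpy()) == 0:
            raise ValueError(f"collinear design: column {c!r} is constant")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(sub[index_a].astype(float), Xc).fit()
    r = partial_correlation(table, region, index_a, index_b, hemisphere=hemisphere)
    return AssociationResult(
        region=region,
        index_a=index_a,
        index_b=index_b,
        coefficient=float(fit.params[index_b]),
        t=float(fit.tvalues[index_b]),
        p=float(fit.pvalues[index_b]),
        partial_r=r,
        n=n,
    )


def partial_correlation(
    table: pd.DataFrame,
    region: str,
    index_a: str,
    index_b: str,
    covariates: Sequence[str] = DEFAULT_PARTIAL_COVARIATES,
    hemisphere: str = "mean",
) -> float:
    """Pearson partial correlation of two indices given covariates.

    Each index is regressed (with intercept) on the covariates and the
    residuals are correlated; with no covariates this is the plain
    Pearson correlation.  Symmetric in the two indices.
    """
    sub = _region_rows(table, region, hemisphere)
    sub = sub.dropna(subset=[index_a, index_b])
    a = sub[index_a].to_numpy(dtype=float)
    b = sub[index_b].to_numpy(dtype=float)
    if covariates:
        Z = np.column_stack([np.ones(len(sub)), _design(sub, covariates).to_numpy()])
        ra = a - Z @ np.linalg.lstsq(Z, a, rcond=None)[0]
        rb = b - Z @ np.linalg.lstsq(Z, b, rcond=None)[0]
    else:
        ra, rb = a - a.mean(), b - b.mean()
    va, vb = ra @ ra, rb @ rb
    if va <= 1e-12 * max(1.0, a @ a) or vb <= 1e-12 * max(1.0, b @ b):
        raise ValueError("zero residual variance; partial correlation undefined")
    return float((ra @ rb) / math.sqrt(va * vb))


def bonferroni_cutoff(alpha: float, m: int) -> tuple[float, float]:
    """Per-test threshold alpha/m, reported truncated to one significant
    figure (the conventional printed form) alongside the exact value.

    Returns ``(truncated, exact)``; e.g. (0.05, 36) -> (0.001, 0.0013888...).
    """
    if m < 1:
        raise ValueError("test count m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    exact = alpha / m
    exponent = math.floor(math.log10(exact))
    truncated = math.floor(exact / 10**exponent) * 10**exponent
    return truncated, exact


def _stars(p: float) -> str:
    out = ""
    for threshold, marker in STAR_TIERS:
        if p < threshold:
            out = marker
    return out


def association_table(
    table: pd.DataFrame,
    index_pairs: Optional[Sequence[tuple]] = None,
    regions: Sequence[str] = ANALYSIS_REGIONS,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_MODEL_COVARIATES,
    hemisphere: str = "mean",
) -> pd.DataFrame:
    """Full association grid: all unordered index pairs x regions.

    Returns a tidy frame (region, index_a, index_b, partial_r, coefficient,
    t, p, stars, n) with star tiers at the conventional printed
    thresholds; the family-wise Bonferroni cutoff for the grid size is
    attached as frame metadata (``attrs``).
    """
    if index_pairs is None:
        index_pairs = list(itertools.combinations(INDEX_COLUMNS, 2))
    if len(table) == 0:
        return pd.DataFrame(
            columns=["region", "index_a", "index_b", "partial_r", "coefficient",
                     "t", "p", "stars", "n"]
        )
    rows = []
    for region in regions:
        for a, b in index_pairs:
            res = adjusted_association(
                table, region, a, b, covariates=covariates, hemisphere=hemisphere
            )
            rows.append(
                dict(
                    region=region,
                    index_a=a,
                    index_b=b,
                    partial_r=res.partial_r,
                    coefficient=res.coefficient,
                    t=res.t,
                    p=res.p,
                    stars=_stars(res.p),
                    n=res.n,
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        cutoff, exact = bonferroni_cutoff(alpha, len(out))
        out.attrs["bonferroni_cutoff"] = cutoff
        out.attrs["bonferroni_exact"] = exact
        out.attrs["n_tests"] = len(out)
        out.attrs["sex_coding"] = "indicator, reference female"
    return out


def render_association_table(grid: pd.DataFrame) -> str:
    """Plain-text rendering: index pairs as rows, regions as columns,
    cells showing the partial correlation with significance stars."""
    if grid.empty:
        return "(empty association grid)"
    regions = list(dict.fromkeys(grid["region"]))
    pairs = list(dict.fromkeys(zip(grid["index_a"], grid["index_b"])))
    lines = ["pair".ljust(18) + "".join(r.rjust(12) for r in regions)]
    for a, b in pairs:
        cells = []
        for region in regions:
            row = grid[
                (grid["region"] == region) & (grid["index_a"] == a) & (grid["index_b"] == b)
            ].iloc[0]
            cells.append(f"{row.partial_r:.2f}{row.stars}".rjust(12))
        lines.append(f"{a}~{b}".ljust(18) + "".join(cells))
    cutoff = grid.attrs.get("bonferroni_cutoff")
    if cutoff is not None:
        lines.append(
            f"adjusted significance level p < {cutoff:g} "
            f"({grid.attrs['n_tests']} tests); "
            "stars: " + ", ".join(f"{m} p<{t:g}" for t, m in STAR_TIERS)
        )
    return "\n".join(lines)
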
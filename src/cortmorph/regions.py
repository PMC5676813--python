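"""Lobar region schemes and the per-subject regional metrics table.

Atlas parcels (Desikan–Killiany gyral parcels by default) are merged into
six analysis regions — frontal, parietal, temporal, occipital, cingulate,
insula — and the four surface indices are computed per region and
hemisphere, then averaged across hemispheres.  The resulting tidy table,
one row per (subject, region, hemisphere in {left, right, mean}), is the
hand-off between the geometry and statistics halves of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .curvature import filter_ic, ic_skew, intrinsic_curvature, principal_curvatures
from .gyrification import compute_lgi
from .io import RegionLabeling
from .thickness import SurfacePair, cortical_thickness, vertex_areas

__all__ = [
    "ANALYSIS_REGIONS",
    "DEFAULT_PARCEL_SCHEME",
    "RegionScheme",
    "merge_parcels",
    "subject_metrics",
    "hemisphere_asymmetry_screen",
    "INDEX_COLUMNS",
]

ANALYSIS_REGIONS = ("frontal", "parietal", "temporal", "occipital", "cingulate", "insula")
INDEX_COLUMNS = ("ic_skew", "ct_mean", "lgi_mean", "sa")

# Conventional gyral-parcel -> lobe assignment.  The composition is a
# declared convention (editable via RegionScheme), not a claim about any
# particular atlas file.
DEFAULT_PARCEL_SCHEME = {
    # frontal (11)
    "superiorfrontal": "frontal",
    "rostralmiddlefrontal": "frontal",
    "caudalmiddlefrontal": "frontal",
    "parsopercularis": "frontal",
    "parstriangularis": "frontal",
    "parsorbitalis": "frontal",
    "lateralorbitofrontal": "frontal",
    "medialorbitofrontal": "frontal",
    "precentral": "frontal",
    "paracentral": "frontal",
    "frontalpole": "frontal",
    # parietal (5)
    "superiorparietal": "parietal",
    "inferiorparietal": "parietal",
    "supramarginal": "parietal",
    "postcentral": "parietal",
    "precuneus": "parietal",
    # temporal (9)
    "superiortemporal": "temporal",
    "middletemporal": "temporal",
    "inferiortemporal": "temporal",
    "bankssts": "temporal",
    "fusiform": "temporal",
    "transversetemporal": "temporal",
    "entorhinal": "temporal",
    "temporalpole": "temporal",
    "parahippocampal": "temporal",
    # occipital (4)
    "lateraloccipital": "occipital",
    "lingual": "occipital",
    "cuneus": "occipital",
    "pericalcarine": "occipital",
    # cingulate (4)
    "rostralanteriorcingulate": "cingulate",
    "caudalanteriorcingulate": "cingulate",
    "posteriorcingulate": "cingulate",
    "isthmuscingulate": "cingulate",
    # insula (1)
    "insula": "insula",
}

DEFAULT_EXCLUDED_PARCELS = ("unknown", "corpuscallosum", "medialwall")


@dataclass
class RegionScheme:
    """Mapping from atlas parcel names to the six analysis regions."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_PARCEL_SCHEME))
    excluded: tuple = DEFAULT_EXCLUDED_PARCELS
    regions: tuple = ANALYSIS_REGIONS

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(self.regions)
        if bad:
            raise ValueError(f"scheme maps parcels to unknown regions: {sorted(bad)}")


def merge_parcels(labeling: RegionLabeling, scheme: Optional[RegionScheme] = None) -> RegionLabeling:
    """Collapse an atlas parcel labeling into the analysis regions.

    Every labeled parcel must appear in the scheme's mapping or its
    exclusion list; an unmapped parcel is an error (silently dropping
    cortex would bias regional sums).  Vertex counts are conserved:
    merged + excluded = total.
    """
    scheme = scheme or RegionScheme()
    present = set(labeling.vertex_labels)
    unmapped = present - set(scheme.mapping) - set(scheme.excluded) - {"unknown"}
    if unmapped:
        raise ValueError(f"parcels not covered by the region scheme: {sorted(unmapped)}")
    out = np.array(
        [scheme.mapping.get(name, "unknown") for name in labeling.vertex_labels],
        dtype=object,
    )
    used = tuple(r for r in scheme.regions if (out == r).any())
    return RegionLabeling(out, used or scheme.regions, labeling.hemisphere_tag)


@dataclass
class MetricConfig:
    """Geometry-stage parameters stamped into every metrics table."""

    curvature_ring: int = 2
    ic_max_radius_factor: float = 1.0
    lgi_closing_diameter: float = 15.0
    lgi_voxel_size: float = 1.0
    lgi_roi_diameter: float = 10.0
    lgi_stride: int = 100
    sa_surface: str = "white"  # which surface carries area (white|pial)
    min_region_vertices: int = 10

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def subject_metrics(
    subject_id: str,
    pairs: dict,
    labelings: dict,
    scheme: Optional[RegionScheme] = None,
    config: Optional[MetricConfig] = None,
    merge: bool = False,
) -> pd.DataFrame:
    """All four indices per region and hemisphere for one subject.

    ``pairs`` maps ``"left"``/``"right"`` to :class:`SurfacePair`;
    ``labelings`` maps the same keys to a :class:`RegionLabeling` (already
    at analysis-region granularity unless ``merge=True``).  Returns rows
    for left, right, and their arithmetic mean, plus per-subject
    ``total_sa`` (hemispheres summed over all regions).  Regions whose IC
    summary has too few valid vertices get NaN there and a flag.
    """
    config = config or MetricConfig()
    scheme = scheme or RegionScheme()
    if set(pairs) != {"left", "right"}:
        raise ValueError("pairs must have exactly the keys 'left' and 'right'")

    hemi_rows: dict = {}
    for hemi in ("left", "right"):
        pair: SurfacePair = pairs[hemi]
        labeling = labelings[hemi]
        if merge:
            labeling = merge_parcels(labeling, scheme)
        if labeling.n_vertices != pair.pial.n_vertices:
            raise ValueError(f"{hemi}: labeling length does not match pial vertex count")

        sa_mesh = pair.white if config.sa_surface == "white" else pair.pial
        areas = vertex_areas(sa_mesh)
        pial_areas = vertex_areas(pair.pial)

        pc = principal_curvatures(pair.pial, ring=config.curvature_ring)
        icf = filter_ic(intrinsic_curvature(pc), pair.pial, config.ic_max_radius_factor)
        ct = cortical_thickness(pair)
        lgi = compute_lgi(
            pair.pial,
            closing_diameter=config.lgi_closing_diameter,
            voxel_size=config.lgi_voxel_size,
            roi_diameter=config.lgi_roi_diameter,
            stride=config.lgi_stride,
        )

        for region in scheme.regions:
            try:
                idx = labeling.vertices_of(region)
            except KeyError:
                idx = np.array([], dtype=np.int64)
            if len(idx) == 0:
                hemi_rows[(region, hemi)] = dict(
                    ic_skew=np.nan, ct_mean=np.nan, lgi_mean=np.nan, sa=np.nan,
                    flagged=True,
                )
                continue
            summary = ic_skew(icf, idx, min_valid=config.min_region_vertices)
            w = areas[idx]
            ct_ok = ct.valid[idx]
            ct_mean = (
                float(np.sum(ct.ct[idx][ct_ok] * w[ct_ok]) / np.sum(w[ct_ok]))
                if ct_ok.any()
                else np.nan
            )
            pw = pial_areas[idx]
            lgi_mean = float(np.sum(lgi.lgi[idx] * pw) / np.sum(pw))
            hemi_rows[(region, hemi)] = dict(
                ic_skew=summary.skew if summary.usable else np.nan,
                ct_mean=ct_mean,
                lgi_mean=lgi_mean,
                sa=float(w.sum()),
                flagged=not summary.usable,
            )

    rows = []
    total_sa = float(
        np.nansum([hemi_rows[(r, h)]["sa"] for r in scheme.regions for h in ("left", "right")])
    )
    for region in scheme.regions:
        for hemi in ("left", "right"):
            d = hemi_rows[(region, hemi)]
            rows.append(
                dict(subject=subject_id, region=region, hemisphere=hemi, total_sa=total_sa, **d)
            )
        L, R = hemi_rows[(region, "left")], hemi_rows[(region, "right")]
        mean_row = dict(subject=subject_id, region=region, hemisphere="mean", total_sa=total_sa)
        for col in INDEX_COLUMNS:
            # hemispheric average for every index, SA included (total SA
            # uses the sum of both hemispheres instead)
            mean_row[col] = 0.5 * (L[col] + R[col])
        mean_row["flagged"] = bool(L["flagged"] or R["flagged"])
        rows.append(mean_row)
    return pd.DataFrame(rows)


def hemisphere_asymmetry_screen(
    table: pd.DataFrame, index: str, alpha: float = 0.002
) -> pd.DataFrame:
    """Paired t-test of left vs right per region for one index.

    Regions with p below ``alpha`` are flagged for hemisphere-separate
    downstream analysis.  Degenerate all-identical pairs give t = 0,
    p = 1 by convention.
    """
    if index not in INDEX_COLUMNS:
        raise KeyError(f"unknown index {index!r}; choose from {INDEX_COLUMNS}")
    out = []
    for region, grp in table.groupby("region", sort=False):
        wide = grp.pivot_table(index="subject", columns="hemisphere", values=index)
        if not {"left", "right"} <= set(wide.columns):
            continue
        paired = wide[["left", "right"]].dropna()
        n = len(paired)
        if n < 3:
            continue
        diffs = paired["right"].to_numpy() - paired["left"].to_numpy()
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = _stats.ttest_rel(paired["right"], paired["left"])
        out.append(
            dict(region=region, index=index, n=n, t=float(t), p=float(p), flagged=p < alpha)
        )
    return pd.DataFrame(out)
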
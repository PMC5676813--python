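"""Pipeline orchestration: metrics extraction over a subject manifest,
association and trajectory stages, with plain-text inter-stage tables and
provenance JSON.

Every stage writes a sidecar ``*.provenance.json`` recording the exact
configuration, package version, and seed, so any two runs with identical
config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, is_dataclass
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .associations import association_table, render_association_table
from .gam import GAMConfig, fitted_age_curves, fit_gam_mixed, trajectory_table
from .io import read_labeling, read_surface
from .regions import MetricConfig, RegionScheme, subject_metrics
from .thickness import SurfacePair

log = logging.getLogger("cortmorph")

MANIFEST_COLUMNS = (
    "subject",
    "white_left", "pial_left", "labels_left",
    "white_right", "pial_right", "labels_right",
)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_provenance(path: Path, config, seed: Optional[int] = None, extra: Optional[dict] = None):
    payload = {
        "package": "cortmorph",
        "version": __version__,
        "config": _jsonable(config),
        "seed": seed,
    }
    if extra:
        payload.update(_jsonable(extra))
    blob = json.dumps(payload, sort_keys=True, indent=2, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, default=str))


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_metrics(
    manifest_path,
    outdir,
    config: Optional[MetricConfig] = None,
    scheme: Optional[RegionScheme] = None,
    subject_table: Optional[str] = None,
    merge: bool = False,
) -> int:
    """Extract the regional metrics table for every subject in a manifest.

    The manifest is a CSV with columns ``subject, white_left, pial_left,
    labels_left, white_right, pial_right, labels_right``.  Per-subject
    failures are logged and collected in a failure manifest rather than
    aborting the run; the exit code is nonzero iff any subject failed.
    """
    config = config or MetricConfig()
    scheme = scheme or RegionScheme()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")

    frames, failures = [], []
    for _, row in manifest.iterrows():
        sid = str(row["subject"])
        t0 = time.time()
        try:
            pairs, labelings = {}, {}
            for hemi in ("left", "right"):
                white = read_surface(row[f"white_{hemi}"], hemisphere_tag=hemi)
                pial = read_surface(row[f"pial_{hemi}"], hemisphere_tag=hemi)
                pairs[hemi] = SurfacePair(white=white, pial=pial)
                labelings[hemi] = read_labeling(row[f"labels_{hemi}"], pial)
            frames.append(
                subject_metrics(sid, pairs, labelings, scheme=scheme, config=config, merge=merge)
            )
            log.info("subject %s done in %.1fs", sid, time.time() - t0)
        except Exception as exc:
            log.error("subject %s failed: %s", sid, exc)
            failures.append({"subject": sid, "error": str(exc)})

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["subject", "region", "hemisphere"])
        log.warning("no subjects processed; writing empty table")
    if subject_table is not None:
        covs = pd.read_csv(subject_table)
        covs["subject"] = covs["subject"].astype(str)
        table = table.merge(covs, on="subject", how="left")

    _write_table(table, outdir / "regional_metrics.tsv")
    pd.DataFrame(failures).to_csv(outdir / "failures.csv", index=False)
    write_provenance(
        outdir / "regional_metrics.provenance.json",
        {"metric_config": config, "scheme_regions": scheme.regions},
        extra={"n_subjects": len(frames), "n_failed": len(failures)},
    )
    return 1 if failures else 0


def run_associate(table_path, outdir, alpha: float = 0.05, hemisphere: str = "mean") -> pd.DataFrame:
    """Association grid (all index pairs x regions) from a metrics table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _read_metrics(table_path)
    grid = association_table(table, alpha=alpha, hemisphere=hemisphere)
    _write_table(grid, outdir / "associations.tsv")
    (outdir / "associations.txt").write_text(render_association_table(grid) + "\n")
    write_provenance(
        outdir / "associations.provenance.json",
        {"alpha": alpha, "hemisphere": hemisphere, **{k: v for k, v in grid.attrs.items()}},
    )
    return grid


def run_trajectories(
    table_path,
    outdir,
    config: Optional[GAMConfig] = None,
    alpha: float = 0.05,
    age_min: Optional[float] = None,
    age_max: Optional[float] = None,
    curves_for: Optional[list] = None,
    hemisphere: str = "mean",
) -> pd.DataFrame:
    """Trajectory grid (Age F/p, Sex t/p, R^2 per region x index) plus
    fitted age curves; optional restricted age range via age_min/age_max."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or GAMConfig()
    table = _read_metrics(table_path)
    if age_min is not None:
        table = table[table["age"] >= age_min]
    if age_max is not None:
        table = table[table["age"] <= age_max]
    grid = trajectory_table(table, config=config, alpha=alpha, hemisphere=hemisphere)
    _write_table(grid, outdir / "trajectories.tsv")

    curve_frames = []
    for index, region in curves_for or []:
        sub = table[(table["region"] == region) & (table["hemisphere"] == hemisphere)]
        fit = fit_gam_mixed(sub, index, config=config)
        cur = fitted_age_curves(fit)
        cur.insert(0, "region", region)
        cur.insert(0, "index", index)
        curve_frames.append(cur)
    if curve_frames:
        _write_table(pd.concat(curve_frames, ignore_index=True), outdir / "age_curves.tsv")
    write_provenance(
        outdir / "trajectories.provenance.json",
        {"gam_config": config, "alpha": alpha, "age_min": age_min, "age_max": age_max},
    )
    return grid


def _read_metrics(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"subject", "region", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    return table
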
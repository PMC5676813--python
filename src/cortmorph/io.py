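"""Surface and label I/O.

Supported surface dialects:

* FreeSurfer binary surface, triangle variant (magic ``0xFFFFFE``,
  big-endian float32 coordinates, optional trailing comment line) — the
  format modern cortical reconstructions emit;
* OFF (ascii);
* PLY (ascii and little-endian binary).

Labelings come either as FreeSurfer ``.label``-style sparse text (one file
per region: header, count, then rows of ``vertex x y z value``) or as a
dense two-column TSV (``vertex<TAB>region``) covering every vertex.

Vertex indices are 0-based everywhere internally.  Coordinates are
millimeters in an arbitrary rigid frame; no voxel-to-RAS geometry is read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import nibabel.freesurfer.io as fsio
import trimesh as _trimesh

from .mesh import MeshValidationError, TriangleMesh, require_valid

__all__ = [
    "RegionLabeling",
    "SurfaceFormatError",
    "read_surface",
    "write_surface",
    "read_labeling",
]

FREESURFER_TRIANGLE_MAGIC = b"\xff\xff\xfe"


class SurfaceFormatError(ValueError):
    """Malformed surface file (bad magic, truncated header, ...)."""


@dataclass
class RegionLabeling:
    """Per-vertex assignment of vertices to named regions.

    ``vertex_labels`` holds one region name per vertex, with ``"unknown"``
    for vertices outside every region.  ``region_names`` is the ordered set
    of real regions (never containing ``"unknown"``).
    """

    vertex_labels: np.ndarray  # (V,) array of str
    region_names: tuple
    hemisphere_tag: Optional[str] = None

    def __post_init__(self) -> None:
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=object)
        self.region_names = tuple(self.region_names)
        extra = set(self.vertex_labels) - set(self.region_names) - {"unknown"}
        if extra:
            raise ValueError(f"labels outside region_names: {sorted(extra)}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_labels)

    def vertices_of(self, region: str) -> np.ndarray:
        """Indices of vertices labeled ``region``."""
        if region != "unknown" and region not in self.region_names:
            raise KeyError(
                f"unknown region {region!r}; available: {list(self.region_names)}"
            )
        return np.where(self.vertex_labels == region)[0]


# ---------------------------------------------------------------------------
# surfaces


def _sniff_format(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(16)
    if head[:3] == FREESURFER_TRIANGLE_MAGIC:
        return "freesurfer"
    if head[:3] in (b"OFF", b"off"):
        return "off"
    if head[:3] == b"ply":
        return "ply"
    raise SurfaceFormatError(
        f"{path}: unrecognized magic bytes {head[:3]!r} at byte offset 0 "
        "(expected FreeSurfer 0xFFFFFE, 'OFF' or 'ply')"
    )


def _read_freesurfer(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic != FREESURFER_TRIANGLE_MAGIC:
        raise SurfaceFormatError(
            f"{path}: bad FreeSurfer magic {magic!r} at byte offset 0; "
            "only the triangle-file variant (0xFFFFFE) is supported"
        )
    try:
        verts, faces = fsio.read_geometry(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise SurfaceFormatError(f"{path}: malformed FreeSurfer surface after byte 3: {exc}")
    return np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def read_surface(
    path: Union[str, os.PathLike],
    format: str = "auto",
    hemisphere_tag: Optional[str] = None,
    boundary_allowed: bool = True,
    validate: bool = True,
) -> TriangleMesh:
    """Read a triangulated surface and validate its integrity.

    ``format='auto'`` sniffs the magic bytes.  Bounded sheets are accepted
    by default (``boundary_allowed=True``); pass False to require a closed
    surface.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "freesurfer":
        verts, faces = _read_freesurfer(path)
    elif format in ("off", "ply"):
        try:
            tm = _trimesh.load(str(path), file_type=format, process=False, force="mesh")
        except Exception as exc:
            raise SurfaceFormatError(f"{path}: malformed {format.upper()} file: {exc}")
        verts = np.asarray(tm.vertices, dtype=np.float64)
        faces = np.asarray(tm.faces, dtype=np.int64)
    else:
        raise ValueError(f"unknown format {format!r}")
    mesh = TriangleMesh(
        verts, faces, hemisphere_tag=hemisphere_tag, boundary_allowed=boundary_allowed
    )
    if validate:
        require_valid(mesh)
    return mesh


def write_surface(mesh: TriangleMesh, path: Union[str, os.PathLike], format: str = "auto") -> None:
    """Write a mesh; the file round-trips through :func:`read_surface` with
    coordinates preserved to 1e-6 mm at unit scale and exact connectivity."""
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower().lstrip(".")
        format = {"off": "off", "ply": "ply"}.get(suffix, "freesurfer")
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    if format == "freesurfer":
        fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    elif format in ("off", "ply"):
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(str(path), file_type=format)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# labelings


def _looks_sparse(path: Path) -> bool:
    with open(path, "r") as fh:
        first = fh.readline()
    return first.startswith("#!ascii") or first.startswith("#")


def _read_sparse_label(path: Path, n_vertices: int) -> np.ndarray:
    """FreeSurfer .label dialect: comment line, count line, then
    ``vertex x y z value`` rows.  Returns the vertex indices."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body:
        raise SurfaceFormatError(f"{path}: empty label file")
    try:
        count = int(body[0].split()[0])
        rows = body[1 : 1 + count]
        idx = np.array([int(r.split()[0]) for r in rows], dtype=np.int64)
    except (ValueError, IndexError) as exc:
        raise SurfaceFormatError(f"{path}: malformed sparse label file: {exc}")
    if len(idx) != count:
        raise SurfaceFormatError(
            f"{path}: header promises {count} rows, found {len(idx)}"
        )
    if len(idx) and (idx.min() < 0 or idx.max() >= n_vertices):
        raise IndexError(
            f"{path}: vertex index {idx.max()} exceeds mesh vertex count {n_vertices}"
        )
    return idx


def read_labeling(
    paths: Union[str, os.PathLike, Sequence[Union[str, os.PathLike]]],
    mesh: TriangleMesh,
    region_names: Optional[Sequence[str]] = None,
) -> RegionLabeling:
    """Read a per-vertex region labeling.

    A single dense TSV assigns every vertex; one or more sparse
    ``.label``-style files each assign one region (named after the file stem
    unless ``region_names`` overrides).  A vertex assigned to two different
    regions is a hard error.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    V = mesh.n_vertices

    if len(paths) == 1 and not _looks_sparse(paths[0]):
        path = paths[0]
        rows = []
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if ln and not ln.startswith("#"):
                    parts = ln.split("\t") if "\t" in ln else ln.split()
                    rows.append((int(parts[0]), parts[1]))
        if len(rows) != V:
            raise SurfaceFormatError(
                f"{path}: dense labeling has {len(rows)} rows but mesh has {V} vertices"
            )
        labels = np.array(["unknown"] * V, dtype=object)
        seen = np.zeros(V, dtype=bool)
        for vi, name in rows:
            if vi < 0 or vi >= V:
                raise IndexError(f"{path}: vertex index {vi} exceeds vertex count {V}")
            if seen[vi]:
                raise ValueError(f"{path}: vertex {vi} assigned twice")
            seen[vi] = True
            labels[vi] = name
        names = tuple(dict.fromkeys(n for n in labels if n != "unknown"))
        return RegionLabeling(labels, names, mesh.hemisphere_tag)

    if region_names is None:
        region_names = [p.stem.split(".")[-1] for p in paths]
    if len(region_names) != len(paths):
        raise ValueError("region_names must match number of label files")

    labels = np.array(["unknown"] * V, dtype=object)
    for path, name in zip(paths, region_names):
        idx = _read_sparse_label(path, V)
        clash = idx[(labels[idx] != "unknown") & (labels[idx] != name)]
        if len(clash):
            prev = labels[clash[0]]
            raise ValueError(
                f"vertex {int(clash[0])} assigned to both {prev!r} and {name!r}"
            )
        labels[idx] = name
    return RegionLabeling(labels, tuple(dict.fromkeys(region_names)), mesh.hemisphere_tag)


def write_labeling(labeling: RegionLabeling, path: Union[str, os.PathLike]) -> None:
    """Write a dense two-column TSV (vertex, region)."""
    with open(path, "w") as fh:
        for i, name in enumerate(labeling.vertex_labels):
            fh.write(f"{i}\t{name}\n")


def write_vertex_field(values: np.ndarray, valid: np.ndarray, path: Union[str, os.PathLike]) -> None:
    """Export a per-vertex scalar field as dense TSV (vertex, value, valid)."""
    with open(path, "w") as fh:
        fh.write("# vertex\tvalue\tvalid\n")
        for i, (v, ok) in enumerate(zip(values, valid)):
            fh.write(f"{i}\t{v:.10g}\t{int(ok)}\n")
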
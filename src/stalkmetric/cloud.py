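"""Labeled point-cloud container and I/O.

The universal currency of the package is :class:`LabeledPointCloud`: N points
with coordinates in reconstruction units, optional per-point colors, unit
normals, and binary semantic labels (0 = background, 1 = stem).

Two on-disk dialects are supported:

* whitespace-separated ASCII (``.xyz``/``.txt``): one point per line, columns
  ``x y z [r g b] [nx ny nz] [label]``, comment lines starting with ``#``.
  Coordinates are written with 8 significant digits.
* PLY, both ``ascii`` and ``binary_little_endian``, restricted to a single
  ``vertex`` element carrying the same optional properties.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LabeledPointCloud",
    "CloudParseError",
    "VoxelDensityStats",
    "read_labeled_cloud",
    "write_labeled_cloud",
    "estimate_normals",
    "voxel_density_stats",
]


class CloudParseError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


@dataclass
class LabeledPointCloud:
    """Point cloud with optional colors, normals and binary labels.

    Parameters
    ----------
    coords
        ``(N, 3)`` float array, reconstruction units (synthetic scenes use mm).
    colors
        Optional ``(N, 3)`` float array in ``[0, 1]``.
    normals
        Optional ``(N, 3)`` unit vectors.
    labels
        Optional ``(N,)`` integer array with values in ``{0, 1}``.
    meta
        Free-form provenance mapping.
    """

    coords: np.ndarray
    colors: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float)
            if self.colors.shape != (n, 3):
                raise ValueError("colors must be (N, 3)")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != (n, 3):
                raise ValueError("normals must be (N, 3)")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit-length (within 1e-6)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must be (N,)")
            if not np.issubdtype(self.labels.dtype, np.integer):
                as_int = self.labels.astype(int)
                if not np.array_equal(as_int, self.labels):
                    raise ValueError("labels must be integers")
                self.labels = as_int
            bad = set(np.unique(self.labels)) - {0, 1}
            if bad:
                raise ValueError(f"labels must be in {{0, 1}}, found {sorted(bad)}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def select(self, mask: np.ndarray) -> "LabeledPointCloud":
        """Sub-cloud of the points selected by a boolean mask or index array."""
        return LabeledPointCloud(
            coords=self.coords[mask],
            colors=None if self.colors is None else self.colors[mask],
            normals=None if self.normals is None else self.normals[mask],
            labels=None if self.labels is None else self.labels[mask],
            meta=dict(self.meta),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LabeledPointCloud":
        """Rigidly transformed copy (normals rotate, labels/colors carry over)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return LabeledPointCloud(
            coords=self.coords @ rotation.T + translation,
            colors=self.colors,
            normals=None if self.normals is None else self.normals @ rotation.T,
            labels=self.labels,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class VoxelDensityStats:
    """Voxel-occupancy summary of a cloud at a given voxel size."""

    total_points: int
    occupied_voxels: int
    mean_points_per_voxel: float
    voxel_size: float


# ---------------------------------------------------------------------------
# ASCII XYZ dialect
# ---------------------------------------------------------------------------

_COLUMN_LAYOUTS = {
    3: (False, False, False),
    4: (False, False, True),
    6: (True, False, False),
    7: (True, False, True),
    9: (True, True, False),
    10: (True, True, True),
}


def _format_ascii_row(values: np.ndarray) -> str:
    return " ".join(f"{v:.8g}" for v in values)


def _write_xyz(cloud: LabeledPointCloud, path: Path) -> None:
    cols = ["x", "y", "z"]
    blocks = [cloud.coords]
    if cloud.colors is not None:
        cols += ["r", "g", "b"]
        blocks.append(cloud.colors)
    if cloud.normals is not None:
        cols += ["nx", "ny", "nz"]
        blocks.append(cloud.normals)
    data = np.hstack(blocks)
    with open(path, "w") as fh:
        fh.write("# columns: " + " ".join(cols + (["label"] if cloud.labels is not None else [])) + "\n")
        if cloud.labels is None:
            for row in data:
                fh.write(_format_ascii_row(row) + "\n")
        else:
            for row, lab in zip(data, cloud.labels):
                fh.write(_format_ascii_row(row) + f" {int(lab)}\n")


def _read_xyz(path: Path) -> LabeledPointCloud:
    declared_cols: Optional[list] = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if stripped.lower().startswith("# columns:"):
                    declared_cols = stripped.split(":", 1)[1].split()
                continue
            parts = stripped.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: malformed record {stripped!r}") from exc
            rows.append((lineno, vals))
    if not rows:
        raise CloudParseError(f"{path}: no data records")
    ncols = len(rows[0][1])
    for lineno, vals in rows:
        if len(vals) != ncols:
            raise CloudParseError(f"{path}:{lineno}: expected {ncols} columns, got {len(vals)}")
    data = np.array([vals for _, vals in rows], dtype=float)

    if declared_cols is not None:
        has_color = "r" in declared_cols
        has_normal = "nx" in declared_cols
        has_label = "label" in declared_cols
        if len(declared_cols) != ncols:
            raise CloudParseError(f"{path}: header declares {len(declared_cols)} columns, file has {ncols}")
    else:
        if ncols not in _COLUMN_LAYOUTS:
            raise CloudParseError(f"{path}: cannot infer layout for {ncols} columns")
        has_color, has_normal, has_label = _COLUMN_LAYOUTS[ncols]

    idx = 3
    colors = normals = labels = None
    if has_color:
        colors = data[:, idx : idx + 3]
        idx += 3
    if has_normal:
        normals = data[:, idx : idx + 3]
        idx += 3
    if has_label:
        raw = data[:, idx]
        labels = raw.astype(int)
        if not np.array_equal(labels, raw):
            raise CloudParseError(f"{path}: non-integer label values")
        bad = set(np.unique(labels)) - {0, 1}
        if bad:
            raise ValueError(f"{path}: unknown label value(s) {sorted(bad)}")
    try:
        return LabeledPointCloud(data[:, :3], colors=colors, normals=normals, labels=labels)
    except ValueError:
        raise


# ---------------------------------------------------------------------------
# PLY dialect (vertex element only)
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _write_ply(cloud: LabeledPointCloud, path: Path, binary: bool) -> None:
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    columns = [cloud.coords[:, 0], cloud.coords[:, 1], cloud.coords[:, 2]]
    if cloud.colors is not None:
        rgb = np.clip(np.rint(cloud.colors * 255.0), 0, 255).astype(np.uint8)
        props += [("red", "uchar"), ("green", "uchar"), ("blue", "uchar")]
        columns += [rgb[:, 0], rgb[:, 1], rgb[:, 2]]
    if cloud.normals is not None:
        props += [("nx", "double"), ("ny", "double"), ("nz", "double")]
        columns += [cloud.normals[:, 0], cloud.normals[:, 1], cloud.normals[:, 2]]
    if cloud.labels is not None:
        props += [("label", "uchar")]
        columns += [cloud.labels.astype(np.uint8)]

    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {cloud.n_points}"]
    header += [f"property {t} {n}" for n, t in props]
    header.append("end_header")
    if binary:
        rec = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t in props])
        body = np.empty(cloud.n_points, dtype=rec)
        for (n, _), col in zip(props, columns):
            body[n] = col
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(body.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            ints = {n for n, t in props if _PLY_DTYPES[t][0] in "iu"}
            for i in range(cloud.n_points):
                parts = []
                for (n, _), col in zip(props, columns):
                    v = col[i]
                    parts.append(str(int(v)) if n in ints else f"{float(v):.8g}")
                fh.write(" ".join(parts) + "\n")


def _read_ply(path: Path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudParseError(f"{path}: not a PLY file")
        fmt = None
        props: list = []
        nvert = None
        in_vertex = False
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise CloudParseError(f"{path}:{lineno}: unexpected end of header")
            tok = line.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    nvert = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise CloudParseError(f"{path}:{lineno}: list properties unsupported")
                props.append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudParseError(f"{path}: unsupported PLY format {fmt!r}")
        if nvert is None:
            raise CloudParseError(f"{path}: no vertex element")
        names = [n for n, _ in props]
        if fmt == "ascii":
            text = fh.read().decode("ascii", "replace").splitlines()
            rows = []
            for off, line in enumerate(text):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != len(props):
                    raise CloudParseError(f"{path}: vertex record {off}: wrong column count")
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise CloudParseError(f"{path}: vertex record {off}: malformed") from exc
                if len(rows) == nvert:
                    break
            if len(rows) != nvert:
                raise CloudParseError(f"{path}: expected {nvert} vertices, got {len(rows)}")
            table = {n: np.array([r[i] for r in rows]) for i, n in enumerate(names)}
        else:
            rec = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t in props])
            raw = fh.read(rec.itemsize * nvert)
            if len(raw) < rec.itemsize * nvert:
                raise CloudParseError(f"{path}: truncated binary body")
            body = np.frombuffer(raw, dtype=rec, count=nvert)
            table = {n: body[n].astype(float) for n in names}

    if not {"x", "y", "z"} <= set(names):
        raise CloudParseError(f"{path}: vertex element lacks x/y/z")
    coords = np.column_stack([table["x"], table["y"], table["z"]])
    colors = normals = labels = None
    if {"red", "green", "blue"} <= set(names):
        colors = np.column_stack([table["red"], table["green"], table["blue"]]) / 255.0
    if {"nx", "ny", "nz"} <= set(names):
        normals = np.column_stack([table["nx"], table["ny"], table["nz"]])
    label_key = next((k for k in ("label", "scalar_label") if k in names), None)
    if label_key is not None:
        raw = table[label_key]
        labels = raw.astype(int)
        bad = set(np.unique(labels)) - {0, 1}
        if bad:
            raise ValueError(f"{path}: unknown label value(s) {sorted(bad)}")
    return LabeledPointCloud(coords, colors=colors, normals=normals, labels=labels)


def _resolve_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("ply", "ply-binary", "xyz-ascii"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() == ".ply":
        return "ply"
    return "xyz-ascii"


def read_labeled_cloud(path, format: Optional[str] = None) -> LabeledPointCloud:
    """Read a labeled point cloud from ``path`` (PLY or ASCII XYZ dialect)."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt.startswith("ply"):
        return _read_ply(path)
    return _read_xyz(path)


def write_labeled_cloud(cloud: LabeledPointCloud, path, format: Optional[str] = None) -> None:
    """Write ``cloud`` to ``path``; re-readable by :func:`read_labeled_cloud`.

    ASCII output carries 8 significant digits. ``format='ply-binary'`` selects
    binary little-endian PLY.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=False)
    elif fmt == "ply-binary":
        _write_ply(cloud, path, binary=True)
    else:
        _write_xyz(cloud, path)


# ---------------------------------------------------------------------------
# Per-point geometry features
# ---------------------------------------------------------------------------


def estimate_normals(cloud: LabeledPointCloud, k: int = 16) -> LabeledPointCloud:
    """Estimate unit surface normals by local covariance eigen-analysis.

    For each point the ``k`` nearest neighbours (excluding the point itself)
    define a local covariance matrix whose smallest-eigenvalue eigenvector is
    the normal. Signs are oriented toward +y (the canonical up direction); a
    normal orthogonal to y is oriented by its largest remaining component.
    """
    n = cloud.n_points
    if k < 3:
        raise ValueError("k must be at least 3")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the point count {n}")
    tree = cKDTree(cloud.coords)
    _, idx = tree.query(cloud.coords, k=k + 1)
    neigh = cloud.coords[idx]                      # (N, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    _, vecs = np.linalg.eigh(cov)                  # ascending eigenvalues
    normals = vecs[:, :, 0]
    # orientation: toward +y, tie-broken by z then x
    ref = normals[:, 1].copy()
    tie = np.abs(ref) < 1e-12
    ref[tie] = normals[tie, 2]
    tie2 = np.abs(ref) < 1e-12
    ref[tie2] = normals[tie2, 0]
    normals = normals * np.where(ref < 0, -1.0, 1.0)[:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return LabeledPointCloud(
        coords=cloud.coords,
        colors=cloud.colors,
        normals=normals,
        labels=cloud.labels,
        meta=dict(cloud.meta),
    )


def voxel_density_stats(cloud: LabeledPointCloud, voxel_size: float = 1.0) -> VoxelDensityStats:
    """Voxel-occupancy density summary.

    The grid is anchored at the cloud's axis-aligned minimum corner with
    half-open voxels ``[lo, lo + s)``. The mean density is
    ``N / occupied_voxels`` so the total point count is conserved.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    keys = np.floor((cloud.coords - cloud.coords.min(axis=0)) / voxel_size).astype(np.int64)
    occupied = np.unique(keys, axis=0).shape[0]
    return VoxelDensityStats(
        total_points=cloud.n_points,
        occupied_voxels=occupied,
        mean_points_per_voxel=cloud.n_points / occupied,
        voxel_size=float(voxel_size),
    )
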
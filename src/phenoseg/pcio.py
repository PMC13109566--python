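"""Labeled point-cloud I/O.

Three on-disk dialects are supported:

- ``ply``  — PLY with vertex properties x, y, z (float) and an optional integer
  ``label`` property. Written as binary_little_endian by default; ASCII and
  binary_little_endian are both accepted on read.
- ``xyzl`` — whitespace-separated ASCII, one point per line, 3 columns
  (``x y z``) or 4 (``x y z label``).
- ``npz``  — compressed numpy container (keys ``coords``, optional ``labels``,
  ``features``); used for internal fixtures.

All coordinates are meters. Labels are the two-class organ encoding used
project-wide: 0 = leaf, 1 = stem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

LABEL_LEAF = 0
LABEL_STEM = 1

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


class PointCloudParseError(ValueError):
    """Malformed file content (bad header, bad row, wrong column count)."""


class PointCloudValidationError(ValueError):
    """Structurally valid file whose content violates the cloud invariants."""


@dataclass
class LabeledPointCloud:
    """N x 3 coordinates in meters with optional per-point labels and features.

    labels, when present, must be in {0 (leaf), 1 (stem)}.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    features: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise PointCloudValidationError(
                f"coords must be N x 3, got shape {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise PointCloudValidationError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            bad = np.where(~np.isfinite(self.coords).all(axis=1))[0]
            raise PointCloudValidationError(
                f"non-finite coordinates at point indices {bad[:10].tolist()}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.coords.shape[0],):
                raise PointCloudValidationError(
                    f"labels length {self.labels.shape} does not match N={self.n_points}")
            bad = np.where((self.labels != LABEL_LEAF) & (self.labels != LABEL_STEM))[0]
            if bad.size:
                raise PointCloudValidationError(
                    f"labels outside {{0,1}} at indices {bad[:10].tolist()}")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.ndim != 2 or self.features.shape[0] != self.coords.shape[0]:
                raise PointCloudValidationError(
                    f"features row count {self.features.shape} does not match N={self.n_points}")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def subset(self, indices: np.ndarray, name: str | None = None) -> "LabeledPointCloud":
        """New cloud restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=np.int64)
        return LabeledPointCloud(
            coords=self.coords[idx],
            labels=None if self.labels is None else self.labels[idx],
            features=None if self.features is None else self.features[idx],
            name=name if name is not None else self.name,
        )

    def height(self) -> float:
        """Vertical (z) extent of the bounding box; the plant height proxy."""
        return float(self.coords[:, 2].max() - self.coords[:, 2].min())


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("ply", "npz"):
        return ext
    if ext in ("xyzl", "xyz", "txt"):
        return "xyzl"
    raise ValueError(f"cannot auto-detect point-cloud format from extension {path.suffix!r}")


def read_point_cloud(path: str | Path, format: str = "auto") -> LabeledPointCloud:
    """Read and validate a labeled point cloud.

    Parameters
    ----------
    path : file path
    format : one of ``ply``, ``xyzl``, ``npz``, ``auto`` (extension-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "xyzl":
        return _read_xyzl(path)
    if fmt == "npz":
        return _read_npz(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_point_cloud(cloud: LabeledPointCloud, path: str | Path,
                      format: str = "auto", ply_ascii: bool = False) -> None:
    """Write a cloud so that :func:`read_point_cloud` recovers it losslessly
    in labels and to at least single precision in coordinates."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "ply":
        _write_ply(cloud, path, ascii=ply_ascii)
    elif fmt == "xyzl":
        _write_xyzl(cloud, path)
    elif fmt == "npz":
        _write_npz(cloud, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------- xyzl text

def _read_xyzl(path: Path) -> LabeledPointCloud:
    coords, labels = [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if ncols is None:
                ncols = len(parts)
                if ncols not in (3, 4):
                    raise PointCloudParseError(
                        f"{path}:{lineno}: expected 3 or 4 columns, got {ncols}")
            if len(parts) != ncols:
                raise PointCloudParseError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(parts)}")
            try:
                coords.append([float(parts[0]), float(parts[1]), float(parts[2])])
                if ncols == 4:
                    labels.append(int(parts[3]))
            except ValueError as exc:
                raise PointCloudParseError(f"{path}:{lineno}: {exc}") from None
    if not coords:
        raise PointCloudParseError(f"{path}: no points found")
    return LabeledPointCloud(
        coords=np.array(coords),
        labels=np.array(labels) if labels else None,
        name=path.stem,
    )


def _write_xyzl(cloud: LabeledPointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        if cloud.labels is None:
            for p in cloud.coords:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        else:
            for p, lab in zip(cloud.coords, cloud.labels):
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {int(lab)}\n")


# ---------------------------------------------------------------- npz

def _read_npz(path: Path) -> LabeledPointCloud:
    with np.load(path) as data:
        return LabeledPointCloud(
            coords=data["coords"],
            labels=data["labels"] if "labels" in data else None,
            features=data["features"] if "features" in data else None,
            name=str(data["name"]) if "name" in data else path.stem,
        )


def _write_npz(cloud: LabeledPointCloud, path: Path) -> None:
    payload = {"coords": cloud.coords, "name": np.str_(cloud.name)}
    if cloud.labels is not None:
        payload["labels"] = cloud.labels
    if cloud.features is not None:
        payload["features"] = cloud.features
    np.savez_compressed(path, **payload)


# ---------------------------------------------------------------- PLY

def _read_ply_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Returns (format, n_vertices, vertex properties, header byte length)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PointCloudParseError("not a PLY file (missing 'ply' magic, line 1)")
    fmt = None
    n_vertices = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    lineno = 1
    while True:
        raw = fh.readline()
        if not raw:
            raise PointCloudParseError(f"unexpected end of PLY header at line {lineno}")
        lineno += 1
        tokens = raw.decode("ascii", errors="replace").split()
        if not tokens:
            continue
        if tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise PointCloudParseError(
                    f"line {lineno}: unsupported PLY format {tokens[1]!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertices = int(tokens[2])
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise PointCloudParseError(
                    f"line {lineno}: list properties on vertices are not supported")
            if tokens[1] not in _PLY_DTYPES:
                raise PointCloudParseError(
                    f"line {lineno}: unknown PLY type {tokens[1]!r}")
            props.append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
    if fmt is None or n_vertices is None:
        raise PointCloudParseError("PLY header missing format or vertex element")
    return fmt, n_vertices, props, fh.tell()


def _read_ply(path: Path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, _ = _read_ply_header(fh)
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise PointCloudParseError(f"PLY vertex element lacks property {axis!r}")
        dtype = np.dtype([(nm, "<" + _PLY_DTYPES[ty]) for nm, ty in props])
        if fmt == "binary_little_endian":
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise PointCloudParseError(
                    f"PLY body truncated: expected {n} vertices")
            rec = np.frombuffer(buf, dtype=dtype, count=n)
        else:
            rows = []
            for i in range(n):
                line = fh.readline()
                parts = line.split()
                if len(parts) != len(props):
                    raise PointCloudParseError(
                        f"PLY ascii vertex row {i}: expected {len(props)} values, "
                        f"got {len(parts)}")
                rows.append(tuple(float(v) for v in parts))
            rec = np.array(rows, dtype=dtype)
    coords = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float64)
    labels = rec["label"].astype(np.int64) if "label" in names else None
    return LabeledPointCloud(coords=coords, labels=labels, name=path.stem)


def _write_ply(cloud: LabeledPointCloud, path: Path, ascii: bool = False) -> None:
    has_labels = cloud.labels is not None
    fmt = "ascii" if ascii else "binary_little_endian"
    header = ["ply", f"format {fmt} 1.0",
              f"element vertex {cloud.n_points}",
              "property float x", "property float y", "property float z"]
    if has_labels:
        header.append("property uchar label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        xyz = cloud.coords.astype(np.float32)
        if ascii:
            for i in range(cloud.n_points):
                row = f"{xyz[i, 0]:.9g} {xyz[i, 1]:.9g} {xyz[i, 2]:.9g}"
                if has_labels:
                    row += f" {int(cloud.labels[i])}"
                fh.write((row + "\n").encode("ascii"))
        else:
            if has_labels:
                rec = np.empty(cloud.n_points,
                               dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                                      ("label", "u1")])
                rec["label"] = cloud.labels.astype(np.uint8)
            else:
                rec = np.empty(cloud.n_points,
                               dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4")])
            rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
            fh.write(rec.tobytes())
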
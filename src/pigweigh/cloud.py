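"""Core point-cloud containers and file I/O.

The universal payload of the pipeline is :class:`PointCloud`: an *ordered*
sequence of (x, y, z) coordinates in meters, expressed in the camera frame of
a top-down depth camera (z grows away from the camera toward the floor, which
lies at a constant plane distance ``L``, 2.7 m in the study setup). Clouds may
carry per-point 8-bit RGB colors used by the color-segmentation filter.

File formats are deliberately minimal: PLY (ASCII and binary little-endian)
for clouds and headered CSV for scale-weight tables. The PLY reader/writer is
implemented on numpy structured arrays so that a binary round trip preserves
float64 coordinates bit-for-bit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "WeightRecord",
    "PointCloudError",
    "PlyParseError",
    "WeightTableError",
    "read_cloud",
    "write_cloud",
    "read_weight_table",
]


class PointCloudError(ValueError):
    """Invalid point-cloud construction or operation."""


class PlyParseError(PointCloudError):
    """Malformed PLY or XYZ[RGB] CSV input."""


class WeightTableError(ValueError):
    """Malformed weight-table CSV input."""


@dataclass(frozen=True)
class PointCloud:
    """Ordered 3D points in meters (camera frame), optional 8-bit RGB colors.

    Parameters
    ----------
    points
        ``(n, 3)`` float64 array of (x, y, z). May be empty (``n == 0``).
    colors
        Optional ``(n, 3)`` uint8 array of (r, g, b), parallel to ``points``.
    source_id
        Free-text provenance tag (file stem, generator id, ...).
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise PointCloudError(f"points must be (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise PointCloudError("points contain non-finite coordinates")
        object.__setattr__(self, "points", pts)
        if self.colors is not None:
            cols = np.asarray(self.colors)
            if cols.shape != (len(pts), 3):
                raise PointCloudError(
                    f"colors shape {cols.shape} does not match {len(pts)} points"
                )
            if cols.dtype != np.uint8:
                if np.any((cols < 0) | (cols > 255)):
                    raise PointCloudError("color channels must lie in [0, 255]")
                cols = cols.astype(np.uint8)
            object.__setattr__(self, "colors", cols)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subsequence of the cloud (boolean mask or sorted integer index)."""
        idx = np.asarray(index)
        return PointCloud(
            self.points[idx],
            self.colors[idx] if self.colors is not None else None,
            self.source_id,
        )

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same colors/provenance, new coordinates (same length)."""
        pts = np.asarray(points, dtype=np.float64)
        if pts.shape != self.points.shape:
            raise PointCloudError("with_points requires an equal-shape array")
        return PointCloud(pts, self.colors, self.source_id)


@dataclass(frozen=True)
class WeightRecord:
    """One scale weighing: animal id, weight in kg, optional ISO capture date."""

    animal_id: str
    scale_weight: float
    capture_date: str = ""

    def __post_init__(self) -> None:
        w = float(self.scale_weight)
        if not np.isfinite(w) or not (0.0 < w < 300.0):
            raise WeightTableError(
                f"scale_weight must lie in (0, 300) kg, got {self.scale_weight!r}"
            )
        object.__setattr__(self, "scale_weight", w)


# --------------------------------------------------------------------------
# PLY

_NUMPY_OF_PLY = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh) -> tuple[str, int, list[tuple[str, str]], list[tuple[str, int]]]:
    """Return (format, n_vertex, vertex properties, other elements)."""

    def readline() -> str:
        raw = fh.readline()
        if not raw:
            raise PlyParseError("unexpected end of file in PLY header")
        return raw.decode("ascii", errors="replace").strip()

    if readline() != "ply":
        raise PlyParseError("not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    others: list[tuple[str, int]] = []
    current = None
    while True:
        line = readline()
        if line == "end_header":
            break
        tok = line.split()
        if not tok or tok[0] == "comment" or tok[0] == "obj_info":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            current = tok[1]
            if current == "vertex":
                n_vertex = int(tok[2])
            else:
                others.append((tok[1], int(tok[2])))
        elif tok[0] == "property":
            if tok[1] == "list":
                if current == "vertex":
                    raise PlyParseError("list properties on vertices are unsupported")
                continue
            if current == "vertex":
                props.append((tok[2], tok[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyParseError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise PlyParseError("PLY header declares no vertex element")
    return fmt, n_vertex, props, others


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, others = _parse_ply_header(fh)
        names = [p for p, _ in props]
        for axis in "xyz":
            if axis not in names:
                raise PlyParseError(f"vertex element lacks property {axis!r}")
        extra = set(names) - {"x", "y", "z", "red", "green", "blue", "alpha"}
        if extra:
            logger.warning("ignoring PLY vertex properties %s in %s", sorted(extra), path)
        if others:
            logger.warning("ignoring non-vertex PLY elements %s in %s", others, path)
        dtype = np.dtype([(p, "<" + _NUMPY_OF_PLY[t]) for p, t in props])
        if fmt == "binary_little_endian":
            data = np.frombuffer(fh.read(dtype.itemsize * n), dtype=dtype, count=n)
            if len(data) != n:
                raise PlyParseError(f"expected {n} vertices, file truncated")
        else:
            rows = []
            for i in range(n):
                line = fh.readline()
                if not line:
                    raise PlyParseError(f"expected {n} vertices, got {i}")
                parts = line.split()
                if len(parts) < len(props):
                    raise PlyParseError(f"vertex record {i} has {len(parts)} fields")
                rows.append(tuple(parts[: len(props)]))
            data = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
    pts = np.column_stack([data[a].astype(np.float64) for a in "xyz"]) if n else np.zeros((0, 3))
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data[c].astype(np.uint8) for c in ("red", "green", "blue")]
        ) if n else np.zeros((0, 3), dtype=np.uint8)
    return PointCloud(pts, colors, source_id=path.stem)


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    if cloud.has_colors:
        props += [("red", "uchar"), ("green", "uchar"), ("blue", "uchar")]
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {n}"]
    header += [f"property {t} {p}" for p, t in props]
    header.append("end_header")
    dtype = np.dtype([(p, "<" + _NUMPY_OF_PLY[t]) for p, t in props])
    data = np.empty(n, dtype=dtype)
    for i, a in enumerate("xyz"):
        data[a] = cloud.points[:, i]
    if cloud.has_colors:
        for i, c in enumerate(("red", "green", "blue")):
            data[c] = cloud.colors[:, i]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            for rec in data:
                fields = [repr(float(rec[a])) for a in "xyz"]
                if cloud.has_colors:
                    fields += [str(int(rec[c])) for c in ("red", "green", "blue")]
                fh.write((" ".join(fields) + "\n").encode("ascii"))


# --------------------------------------------------------------------------
# CSV clouds

def _read_csv_cloud(path: Path) -> PointCloud:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PlyParseError(f"{path}: empty CSV") from None
        cols = [h.strip().lower() for h in header]
        try:
            ix, iy, iz = cols.index("x"), cols.index("y"), cols.index("z")
        except ValueError:
            raise PlyParseError(f"{path}: CSV header must contain x,y,z columns") from None
        has_rgb = all(c in cols for c in ("r", "g", "b"))
        rgb_idx = [cols.index(c) for c in ("r", "g", "b")] if has_rgb else []
        pts, colors = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                pts.append((float(row[ix]), float(row[iy]), float(row[iz])))
                if has_rgb:
                    colors.append(tuple(int(row[j]) for j in rgb_idx))
            except (ValueError, IndexError):
                raise PlyParseError(f"{path}: malformed record at line {lineno}: {row!r}") from None
    return PointCloud(
        np.array(pts, dtype=np.float64).reshape(-1, 3),
        np.array(colors, dtype=np.uint8).reshape(-1, 3) if has_rgb else None,
        source_id=path.stem,
    )


def _write_csv_cloud(cloud: PointCloud, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if cloud.has_colors:
            writer.writerow(["x", "y", "z", "r", "g", "b"])
            for p, c in zip(cloud.points, cloud.colors):
                writer.writerow([repr(float(v)) for v in p] + [int(v) for v in c])
        else:
            writer.writerow(["x", "y", "z"])
            for p in cloud.points:
                writer.writerow([repr(float(v)) for v in p])


# --------------------------------------------------------------------------
# Public I/O

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("ply", "csv"):
            raise ValueError(f"unknown cloud format {fmt!r}; use 'ply' or 'csv'")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return "ply"
    if suffix in (".csv", ".xyz", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer cloud format from {path.name!r}; pass format=")


def read_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from PLY (ASCII or binary little-endian) or XYZ[RGB] CSV.

    Point order and coordinate values are preserved exactly; colors are
    populated iff present in the file.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    return _read_ply(path) if fmt == "ply" else _read_csv_cloud(path)


def write_cloud(
    cloud: PointCloud,
    path: str | Path,
    format: str | None = None,
    binary: bool = True,
) -> None:
    """Write a cloud so that :func:`read_cloud` recovers it.

    Binary PLY is lossless for float64 coordinates; ASCII PLY and CSV use
    ``repr`` round-tripping, which is also exact for float64.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    else:
        _write_csv_cloud(cloud, path)


def read_weight_table(path: str | Path) -> list[WeightRecord]:
    """Read a scale-weight CSV with header ``animal_id,weight_kg[,date]``.

    Raises :class:`WeightTableError` citing the row number for non-numeric or
    out-of-range weights.
    """
    path = Path(path)
    records: list[WeightRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise WeightTableError(f"{path}: empty weight table") from None
        try:
            id_col = header.index("animal_id")
        except ValueError:
            raise WeightTableError(f"{path}: missing 'animal_id' column") from None
        weight_col = next(
            (header.index(c) for c in ("weight_kg", "weight", "scale_weight") if c in header),
            None,
        )
        if weight_col is None:
            raise WeightTableError(f"{path}: missing weight column (weight_kg)")
        date_col = next((header.index(c) for c in ("date", "capture_date") if c in header), None)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                weight = float(row[weight_col])
            except (ValueError, IndexError):
                raise WeightTableError(
                    f"{path}: non-numeric weight at row {lineno}: {row!r}"
                ) from None
            try:
                records.append(
                    WeightRecord(
                        animal_id=row[id_col].strip(),
                        scale_weight=weight,
                        capture_date=row[date_col].strip() if date_col is not None and date_col < len(row) else "",
                    )
                )
            except WeightTableError as exc:
                raise WeightTableError(f"{path}: row {lineno}: {exc}") from None
    return records
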
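"""Readers and writers for the pipeline's on-disk formats.

Electrograms and electrode coordinates travel as headed CSV (comma
separator, ``.`` decimal); meshes as ASCII PLY (canonical) or legacy ASCII
VTK POLYDATA (for visualization tools); tip-density matrices as bare 7x7
CSV; run configuration as YAML.  Voltages are millivolts, coordinates
millimetres, matching clinical-export conventions.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, GeometryError, UsageError

SPLINES = tuple(string.ascii_uppercase[:8])  # A..H
ELECTRODES = tuple(range(1, 9))  # 1..8
BASKET_CHANNELS = tuple(f"{s}{e}" for s in SPLINES for e in ELECTRODES)


@dataclass
class ElectrogramSet:
    """Multichannel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in mV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Per-channel identifiers.  Basket channels are named ``A1``..``H8``
        (spline letter + electrode number); any other label is treated as a
        surface-ECG or auxiliary intracardiac channel.
    """

    samples: np.ndarray
    fs: float = 1000.0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise UsageError("samples must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise UsageError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.labels) != self.samples.shape[0]:
            raise UsageError("one label per channel required")
        basket = [l for l in self.labels if l in BASKET_CHANNELS]
        if len(basket) != len(set(basket)):
            dupes = sorted({l for l in basket if basket.count(l) > 1})
            raise FormatError(f"duplicate basket channel label(s): {dupes}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise UsageError(f"no channel labelled {label!r}") from None

    def basket_labels(self) -> list[str]:
        return [l for l in self.labels if l in BASKET_CHANNELS]


@dataclass(frozen=True)
class BasketLayout:
    """Map (spline, electrode) -> channel row of an :class:`ElectrogramSet`.

    The basket carries 8 splines (A..H) of 8 electrodes (1..8); the layout
    must be a bijection onto the 64 basket channels.
    """

    channel_index: dict[tuple[str, int], int]

    def __post_init__(self) -> None:
        keys = set(self.channel_index)
        expected = {(s, e) for s in SPLINES for e in ELECTRODES}
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise GeometryError(
                f"layout must cover exactly the 64 basket channels; "
                f"missing={missing[:4]}... extra={extra[:4]}..."
                if len(missing) > 4 or len(extra) > 4
                else f"layout must cover exactly the 64 basket channels; "
                f"missing={missing} extra={extra}"
            )
        rows = list(self.channel_index.values())
        if len(set(rows)) != 64:
            raise GeometryError("layout rows must be distinct")

    @classmethod
    def from_labels(cls, labels: list[str]) -> "BasketLayout":
        index: dict[tuple[str, int], int] = {}
        for row, label in enumerate(labels):
            if label in BASKET_CHANNELS:
                index[(label[0], int(label[1]))] = row
        return cls(index)

    def matrix(self, samples: np.ndarray) -> np.ndarray:
        """Reorder channels to a (8 splines, 8 electrodes, n_samples) block."""
        rows = np.array(
            [[self.channel_index[(s, e)] for e in ELECTRODES] for s in SPLINES]
        )
        return samples[rows]


@dataclass
class ElectrodeGeometry:
    """3-D coordinates (mm) of the 64 basket electrodes."""

    coords: dict[tuple[str, int], np.ndarray]

    def __post_init__(self) -> None:
        expected = {(s, e) for s in SPLINES for e in ELECTRODES}
        keys = set(self.coords)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise GeometryError(
                f"electrode set incomplete; missing={missing} extra={extra}"
            )
        pts = self.as_array()
        if not np.all(np.isfinite(pts)):
            raise GeometryError("non-finite electrode coordinate")
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise GeometryError("coincident electrode coordinates")

    def as_array(self) -> np.ndarray:
        """Coordinates as a (64, 3) array in spline-major (A1..A8, B1..) order."""
        return np.array(
            [self.coords[(s, e)] for s in SPLINES for e in ELECTRODES], dtype=float
        )

    @classmethod
    def from_array(cls, pts: np.ndarray) -> "ElectrodeGeometry":
        pts = np.asarray(pts, dtype=float).reshape(64, 3)
        keys = [(s, e) for s in SPLINES for e in ELECTRODES]
        return cls({k: pts[i] for i, k in enumerate(keys)})


@dataclass
class TriMesh:
    """A triangle mesh: vertices (mm), faces (vertex-index triples) and
    optional named per-vertex scalar fields."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face index out of range")
        if self.faces.size and np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise GeometryError("degenerate face with repeated vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted lexicographically."""
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        return np.unique(e, axis=0)

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm


@dataclass
class AnalysisConfig:
    """All tunable knobs of the pipeline in one place.

    Defaults follow the mapping protocol: 1.5-25 Hz fourth-order band-pass,
    QRS template window 100 ms before to 150 ms after the R peak, Welch PSD
    with 2048-sample Hann segments at 50 % overlap, dominant-frequency search
    in the physiological 2-12 Hz fibrillation band, 4x lattice interpolation,
    3 subdivision rounds, >=3-cycle persistence, 10-sample frame stride.
    """

    band_low_hz: float = 1.5
    band_high_hz: float = 25.0
    filter_order: int = 4
    qrs_pre_ms: float = 100.0
    qrs_post_ms: float = 150.0
    welch_nperseg: int = 2048
    welch_overlap: float = 0.5
    df_low_hz: float = 2.0
    df_high_hz: float = 12.0
    interpolation_factor: int = 4
    subdivision_rounds: int = 3
    persistence_cycles: float = 3.0
    frame_stride: int = 10
    electrode_spacing_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            self.band_low_hz, self.band_high_hz, self.filter_order,
            self.qrs_pre_ms, self.qrs_post_ms, self.welch_nperseg,
            self.df_low_hz, self.df_high_hz, self.interpolation_factor,
            self.subdivision_rounds, self.persistence_cycles,
            self.frame_stride, self.electrode_spacing_mm,
        ]
        if any(v <= 0 for v in positive):
            raise UsageError("all numeric configuration fields must be positive")
        if not 0 < self.welch_overlap < 1:
            raise UsageError("welch_overlap must lie in (0, 1)")
        if self.band_low_hz >= self.band_high_hz:
            raise UsageError("band_low_hz must be below band_high_hz")
        if self.df_low_hz >= self.df_high_hz:
            raise UsageError("df_low_hz must be below df_high_hz")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# electrogram CSV

def read_electrograms(path: str | Path, fs: float = 1000.0) -> ElectrogramSet:
    """Read an electrogram CSV: header of channel labels, one row per sample,
    optional leading ``time_ms`` column validated against *fs*."""
    try:
        df = pd.read_csv(path, sep=",")
    except Exception as exc:  # ragged rows, empty file, ...
        raise FormatError(f"cannot parse electrogram CSV {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError("electrogram CSV has no header")
    labels = [str(c) for c in df.columns]
    if labels and labels[0] == "time_ms":
        t = df.pop("time_ms").to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, 1000.0 / fs, atol=1e-6):
            raise FormatError(
                f"time_ms column inconsistent with fs={fs} Hz "
                f"(observed step {np.median(dt):.6g} ms)"
            )
        labels = labels[1:]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise FormatError(f"non-numeric cell in column {col!r} at data row {row}")
    samples = df.to_numpy(dtype=float).T
    return ElectrogramSet(samples=samples, fs=fs, labels=labels)


def write_electrograms(
    egm: ElectrogramSet, path: str | Path, time_column: bool = False
) -> None:
    df = pd.DataFrame(egm.samples.T, columns=egm.labels)
    if time_column:
        df.insert(0, "time_ms", np.arange(egm.n_samples) * 1000.0 / egm.fs)
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# electrode coordinate CSV

def read_electrode_coordinates(path: str | Path) -> ElectrodeGeometry:
    """Read electrode coordinates from a CSV with columns
    ``spline,electrode,x_mm,y_mm,z_mm``."""
    df = pd.read_csv(path, sep=",")
    required = {"spline", "electrode", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"coordinate CSV must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    coords: dict[tuple[str, int], np.ndarray] = {}
    for _, row in df.iterrows():
        key = (str(row["spline"]).strip(), int(row["electrode"]))
        if key in coords:
            raise FormatError(f"duplicate electrode {key}")
        coords[key] = np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
    return ElectrodeGeometry(coords)


def write_electrode_coordinates(geom: ElectrodeGeometry, path: str | Path) -> None:
    rows = [
        {"spline": s, "electrode": e, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
        for (s, e), p in sorted(geom.coords.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# meshes: ASCII PLY (canonical) and legacy ASCII VTK POLYDATA

def write_mesh(mesh: TriMesh, path: str | Path, format: str = "ply") -> None:
    if format == "ply":
        _write_ply(mesh, Path(path))
    elif format == "vtk":
        _write_vtk(mesh, Path(path))
    else:
        raise UsageError(f"unknown mesh format {format!r}; use 'ply' or 'vtk'")


def read_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "ply":
        return _read_ply(path)
    if format == "vtk":
        return _read_vtk(path)
    raise UsageError(f"unknown mesh format {format!r}; use 'ply' or 'vtk'")


def _write_ply(mesh: TriMesh, path: Path) -> None:
    names = list(mesh.vertex_scalars)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        *[f"property double {n}" for n in names],
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    cols = [mesh.vertices] + [
        np.asarray(mesh.vertex_scalars[n], dtype=float).reshape(-1, 1) for n in names
    ]
    data = np.hstack(cols)
    for row in data:
        lines.append(" ".join(f"{v:.12g}" for v in row))
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> TriMesh:
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise FormatError(f"{path} is not a PLY file")
    n_vert = n_face = 0
    scalar_names: list[str] = []
    i = 1
    element = None
    while i < len(text):
        tok = text[i].split()
        i += 1
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise FormatError("only ASCII PLY is supported")
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            if tok[2] not in ("x", "y", "z"):
                scalar_names.append(tok[2])
        elif tok[0] == "end_header":
            break
    body = text[i:]
    vdata = np.array([[float(v) for v in body[k].split()] for k in range(n_vert)])
    faces = []
    for k in range(n_vert, n_vert + n_face):
        tok = body[k].split()
        if int(tok[0]) != 3:
            raise FormatError("only triangle faces are supported")
        faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
    scalars = {
        name: vdata[:, 3 + j] for j, name in enumerate(scalar_names)
    }
    return TriMesh(vertices=vdata[:, :3], faces=np.array(faces), vertex_scalars=scalars)


def _write_vtk(mesh: TriMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "phasebasket mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    for p in mesh.vertices:
        lines.append(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if mesh.vertex_scalars:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, values in mesh.vertex_scalars.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.12g}" for v in np.asarray(values, dtype=float))
    path.write_text("\n".join(lines) + "\n")


def _read_vtk(path: Path) -> TriMesh:
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    try:
        k = next(i for i, l in enumerate(lines) if l.startswith("POINTS"))
    except StopIteration:
        raise FormatError(f"{path}: no POINTS section") from None
    n_vert = int(lines[k].split()[1])
    flat: list[float] = []
    i = k + 1
    while len(flat) < 3 * n_vert:
        flat.extend(float(v) for v in lines[i].split())
        i += 1
    vertices = np.array(flat).reshape(n_vert, 3)
    k = next(i for i, l in enumerate(lines) if l.startswith("POLYGONS"))
    n_face = int(lines[k].split()[1])
    faces = []
    for j in range(n_face):
        tok = lines[k + 1 + j].split()
        faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
    scalars: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        if lines[i].startswith("SCALARS"):
            name = lines[i].split()[1]
            vals: list[float] = []
            j = i + 2  # skip LOOKUP_TABLE
            while len(vals) < n_vert:
                vals.extend(float(v) for v in lines[j].split())
                j += 1
            scalars[name] = np.array(vals)
            i = j
        else:
            i += 1
    return TriMesh(vertices=vertices, faces=np.array(faces), vertex_scalars=scalars)


# ---------------------------------------------------------------------------
# density matrices

def write_density(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",", fmt="%.9g")


def read_density(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path, delimiter=",", ndmin=2)
    if m.shape != (7, 7):
        raise FormatError(f"density matrix must be 7x7; got {m.shape}")
    return m
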
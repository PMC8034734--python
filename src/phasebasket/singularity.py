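"""Phase-map construction and phase-singularity (spiral-tip) detection.

A phase singularity is a point around which the instantaneous phase winds
by +-2pi; it marks the tip of a spiral (rotor) wave.  Detection uses the
discrete winding number: the wrapped phase differences around a closed
loop sum to an exact multiple of 2pi, and a loop enclosing a singularity
yields +-1.

2D maps are built on a 29x29 lattice — three points inserted between
every pair of neighbouring electrodes in each direction by bilinear
interpolation of the recomposed signal — and every elementary lattice
cell is tested.  3D maps interpolate the recomposed signal
barycentrically onto the refined basket mesh and test every refined face.
Because interpolation and the Hilbert transform are both linear, the
analytic signal is computed once per electrode and interpolated as a
complex field; this is identical to interpolating the recomposed signal
and transforming afterwards.

Charge sign convention: +1 is counterclockwise rotation in (spline,
electrode) axes for 2D, and counterclockwise as seen from outside the
closed basket for 3D.  On a closed mesh the detected charges always sum
to zero (every edge is traversed once in each direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .geometry import BasketMesh, GridMesh2D
from .io_formats import BasketLayout
from .recompose import wrap_phase

LATTICE_N = 29  # 8 electrodes with 3 inserted points per interval: 4*7+1


@dataclass
class PhaseFrame2D:
    """Wrapped phase on the 29x29 lattice at one time sample.

    ``phases[ix, iy]`` with ix along splines (x axis) and iy along
    electrodes (y axis); lattice spacing is 1/4 electrode spacing.
    """

    phases: np.ndarray
    time_ms: float

    def __post_init__(self) -> None:
        if self.phases.shape != (LATTICE_N, LATTICE_N):
            raise UsageError(f"2D phase frame must be {LATTICE_N}x{LATTICE_N}")


@dataclass
class PhaseFrame3D:
    """Wrapped phase per refined basket-mesh vertex at one time sample."""

    phases: np.ndarray
    time_ms: float


@dataclass
class PhaseSingularity:
    """One detected spiral tip.

    ``x``/``y`` are grid coordinates in electrode-spacing units (for 3D
    detections these are the unfolded coordinates of the ancestral face;
    wrap-column tips use x in [7, 8] and pole tips pseudo-coordinates
    outside [0, 7]).  ``region`` is ('sub', i, j), ('wrap', i, 8) or
    ('pole', which, -1).
    """

    frame: int
    time_ms: float
    charge: int
    x: float
    y: float
    region: tuple
    face: int | None = None
    lambdas: tuple | None = None


@dataclass
class Track:
    """A singularity followed through consecutive frames."""

    tips: list[PhaseSingularity]

    @property
    def charge(self) -> int:
        return self.tips[0].charge

    @property
    def duration_ms(self) -> float:
        return self.tips[-1].time_ms - self.tips[0].time_ms

    @property
    def mean_position(self) -> np.ndarray:
        return np.array([[t.x, t.y] for t in self.tips]).mean(axis=0)


@dataclass
class TipDensityMatrix:
    """7x7 occupancy map: fraction of frames in which each inter-electrode
    sub-square (i = electrode pair, j = spline pair, both 1..7) contained
    at least one tip.  Tips in the wraparound column or pole caps are
    tallied separately in ``off_matrix``."""

    matrix: np.ndarray
    total_frames: int
    off_matrix: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (7, 7):
            raise UsageError("tip density matrix must be 7x7")


# ---------------------------------------------------------------------------
# frames


def _interp_matrix(factor: int = 4, n: int = 8) -> np.ndarray:
    """Linear-interpolation matrix from n nodes to factor*(n-1)+1 points."""
    fine = np.arange(factor * (n - 1) + 1) / factor
    u = np.zeros((fine.size, n))
    j = np.clip(np.floor(fine).astype(int), 0, n - 2)
    frac = fine - j
    u[np.arange(fine.size), j] = 1 - frac
    u[np.arange(fine.size), j + 1] += frac
    return u


def build_frames_2d(
    recomposed: np.ndarray,
    layout: BasketLayout,
    fs: float,
    stride: int = 10,
) -> list[PhaseFrame2D]:
    """Bilinearly interpolate the 64 recomposed channels onto the 29x29
    lattice and return the wrapped phase every *stride* samples.

    The analytic signal of each electrode channel is computed over the
    full record; lattice phases are the angles of the bilinearly
    interpolated complex field (equivalent, by linearity, to interpolating
    first and applying the Hilbert transform after).
    """
    from .recompose import analytic_signal

    if stride < 1:
        raise UsageError("stride must be >= 1")
    block = layout.matrix(np.asarray(recomposed, dtype=float))  # (8, 8, T)
    z = analytic_signal(block.reshape(64, -1)).reshape(block.shape)
    idx = np.arange(0, block.shape[-1], stride)
    u = _interp_matrix()
    zf = np.einsum("ia,jb,abt->ijt", u, u, z[:, :, idx])
    frames = [
        PhaseFrame2D(
            phases=wrap_phase(np.angle(zf[:, :, k])),
            time_ms=idx[k] * 1000.0 / fs,
        )
        for k in range(idx.size)
    ]
    return frames


def build_frames_3d(
    recomposed: np.ndarray,
    layout: BasketLayout,
    basket: BasketMesh,
    fs: float,
    stride: int = 10,
) -> list[PhaseFrame3D]:
    """Interpolate the 64 recomposed channels onto every refined basket
    vertex (barycentric over the ancestral electrodes) and return wrapped
    phases every *stride* samples."""
    from .recompose import analytic_signal

    if stride < 1:
        raise UsageError("stride must be >= 1")
    rec = np.asarray(recomposed, dtype=float)
    block = layout.matrix(rec).reshape(64, -1)  # spline-major electrode order
    z = analytic_signal(block)
    idx = np.arange(0, block.shape[-1], stride)
    zv = basket.vertex_weights @ z[:, idx]  # (n_vertices, n_frames)
    return [
        PhaseFrame3D(
            phases=wrap_phase(np.angle(zv[:, k])),
            time_ms=idx[k] * 1000.0 / fs,
        )
        for k in range(idx.size)
    ]


# ---------------------------------------------------------------------------
# winding numbers


def winding_number(loop_phases: np.ndarray) -> int:
    """Topological charge of an ordered closed loop of phases:
    (1/2pi) * sum of wrapped consecutive differences, rounded to the
    nearest integer (the sum is an exact multiple of 2pi up to float
    error)."""
    theta = np.asarray(loop_phases, dtype=float)
    if theta.size < 3:
        raise UsageError("a loop needs at least 3 phases")
    d = wrap_phase(np.diff(np.concatenate([theta, theta[:1]])))
    return int(np.rint(d.sum() / (2 * np.pi)))


def detect_ps_2d(frame: PhaseFrame2D, frame_index: int = 0) -> list[PhaseSingularity]:
    """Winding number around every elementary lattice cell (28x28),
    counterclockwise in (electrode, spline) axes — the orientation that
    agrees with the outward-oriented 3D detection on a standard basket;
    cells with charge +-1 yield a singularity at the cell centre."""
    p = frame.phases
    d1 = wrap_phase(p[:-1, 1:] - p[:-1, :-1])  # (x, y) -> (x, y+1)
    d2 = wrap_phase(p[1:, 1:] - p[:-1, 1:])  # -> (x+1, y+1)
    d3 = wrap_phase(p[1:, :-1] - p[1:, 1:])  # -> (x+1, y)
    d4 = wrap_phase(p[:-1, :-1] - p[1:, :-1])  # -> (x, y)
    charge = np.rint((d1 + d2 + d3 + d4) / (2 * np.pi)).astype(int)
    out = []
    for ix, iy in zip(*np.nonzero(charge)):
        x = (ix + 0.5) / 4.0
        y = (iy + 0.5) / 4.0
        region = ("sub", min(int(y), 6) + 1, min(int(x), 6) + 1)
        out.append(
            PhaseSingularity(
                frame=frame_index,
                time_ms=frame.time_ms,
                charge=int(charge[ix, iy]),
                x=x,
                y=y,
                region=region,
            )
        )
    return out


def _unfolded_coords(basket: BasketMesh, face: int) -> tuple[float, float]:
    """Unfolded (x, y) grid coordinates of a refined face via its level-0
    ancestor; wrap-column faces land in x in [7, 8], pole faces get
    pseudo-coordinates just outside the grid."""
    coord = basket.refined_face_barycentric_in_ancestor(face)
    anc = coord.face
    region = basket.region_of_level0_face(anc)
    if region[0] == "pole":
        x = 3.5
        y = -0.5 if region[1] == 0 else 7.5
        return x, y
    # side face: reconstruct the 2D sub-square corner coordinates
    j = anc // 14  # spline pair 0..7
    i = (anc % 14) // 2  # electrode pair 0..6
    second = anc % 2
    a1 = np.array([j, i])
    b1 = np.array([j + 1, i])
    b2 = np.array([j + 1, i + 1])
    a2 = np.array([j, i + 1])
    tri = (a1, b1, b2) if second == 0 else (a1, b2, a2)
    lam = np.asarray(coord.lambdas)
    pos = lam[0] * tri[0] + lam[1] * tri[1] + lam[2] * tri[2]
    return float(pos[0]), float(pos[1])


def detect_ps_3d(
    basket: BasketMesh, frame: PhaseFrame3D, frame_index: int = 0
) -> list[PhaseSingularity]:
    """Winding number around every refined face (vertices in face order,
    which is outward-consistent); faces with charge +-1 yield a
    singularity at the face centroid."""
    theta = np.asarray(frame.phases, dtype=float)
    faces = basket.refined.faces
    if theta.size != basket.refined.n_vertices:
        raise UsageError("one phase per refined vertex required")
    t0, t1, t2 = theta[faces[:, 0]], theta[faces[:, 1]], theta[faces[:, 2]]
    total = wrap_phase(t1 - t0) + wrap_phase(t2 - t1) + wrap_phase(t0 - t2)
    charge = np.rint(total / (2 * np.pi)).astype(int)
    out = []
    for fi in np.flatnonzero(charge):
        x, y = _unfolded_coords(basket, int(fi))
        region = basket.region_of_refined_face(int(fi))
        out.append(
            PhaseSingularity(
                frame=frame_index,
                time_ms=frame.time_ms,
                charge=int(charge[fi]),
                x=x,
                y=y,
                region=region,
                face=int(fi),
                lambdas=(1 / 3, 1 / 3, 1 / 3),
            )
        )
    return out


# ---------------------------------------------------------------------------
# tracking and density


def track_singularities(
    ps_per_frame: list[list[PhaseSingularity]],
    frame_dt_ms: float,
    t_cl_ms: float,
    min_cycles: float = 3.0,
    max_jump: float = 1.0,
    max_gap_frames: int = 1,
) -> list[Track]:
    """Associate tips across frames and keep persistent tracks.

    Greedy nearest-neighbour association: at each frame, candidate pairs
    (open track, new tip) of matching charge within *max_jump* electrode
    spacings are linked smallest-distance first; tracks tolerate gaps of
    up to *max_gap_frames* missed frames.  Tracks whose duration reaches
    ``min_cycles * t_cl_ms`` are returned.
    """
    open_tracks: list[Track] = []
    finished: list[Track] = []
    for f, tips in enumerate(ps_per_frame):
        still_open = []
        for tr in open_tracks:
            if f - tr.tips[-1].frame > max_gap_frames + 1:
                finished.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        pairs = []
        for ti, tip in enumerate(tips):
            for ki, tr in enumerate(open_tracks):
                last = tr.tips[-1]
                if last.charge != tip.charge:
                    continue
                dist = float(np.hypot(tip.x - last.x, tip.y - last.y))
                if dist <= max_jump:
                    pairs.append((dist, ki, ti))
        pairs.sort()
        used_tracks: set[int] = set()
        used_tips: set[int] = set()
        for dist, ki, ti in pairs:
            if ki in used_tracks or ti in used_tips:
                continue
            open_tracks[ki].tips.append(tips[ti])
            used_tracks.add(ki)
            used_tips.add(ti)
        for ti, tip in enumerate(tips):
            if ti not in used_tips:
                open_tracks.append(Track(tips=[tip]))
    finished.extend(open_tracks)
    min_duration = min_cycles * t_cl_ms
    return [tr for tr in finished if tr.duration_ms >= min_duration]


def tip_density(
    ps_per_frame: list[list[PhaseSingularity]], total_frames: int
) -> TipDensityMatrix:
    """7x7 occupancy fractions: entry (i, j) is the fraction of frames in
    which sub-square (i, j) contained at least one tip.  Wrap-column and
    pole-cap tips are tallied off-matrix."""
    if total_frames <= 0:
        raise UsageError("total_frames must be positive")
    counts = np.zeros((7, 7))
    off: dict[str, int] = {}
    for tips in ps_per_frame:
        seen: set[tuple[int, int]] = set()
        seen_off: set[str] = set()
        for tip in tips:
            if tip.region[0] == "sub":
                seen.add((tip.region[1], tip.region[2]))
            else:
                seen_off.add(f"{tip.region[0]}_{tip.region[1]}")
        for i, j in seen:
            counts[i - 1, j - 1] += 1
        for key in seen_off:
            off[key] = off.get(key, 0) + 1
    return TipDensityMatrix(
        matrix=counts / total_frames, total_frames=total_frames, off_matrix=off
    )


__all__ = [
    "LATTICE_N",
    "PhaseFrame2D",
    "PhaseFrame3D",
    "PhaseSingularity",
    "Track",
    "TipDensityMatrix",
    "build_frames_2d",
    "build_frames_3d",
    "winding_number",
    "detect_ps_2d",
    "detect_ps_3d",
    "track_singularities",
    "tip_density",
]
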
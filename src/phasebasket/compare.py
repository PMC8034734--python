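"""Quantitative 2D-vs-3D comparison.

The central question: does unfolding the curved basket into a flat 8x8
grid move spiral tips?  The comparison operates on the 7x7 tip-density
matrices via the Pearson correlation over a region mask (full matrix,
pole rows i in {1,7}, equator row i=4, or the entries owning the highest/
lowest-curvature vertices), the distance between the density maxima, and
paired nonparametric statistics across cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, UsageError
from .geometry import BasketMesh, CurvatureField, GridMesh2D, barycentric_position
from .singularity import PhaseSingularity, TipDensityMatrix


@dataclass(frozen=True)
class RegionMask:
    """A subset of the 7x7 density-matrix entries (1-based (i, j))."""

    entries: frozenset
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.entries:
            raise UsageError("region mask may not be empty")
        for i, j in self.entries:
            if not (1 <= i <= 7 and 1 <= j <= 7):
                raise UsageError(f"mask entry ({i}, {j}) outside 1..7 x 1..7")

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        ij = np.array(sorted(self.entries)) - 1
        return ij[:, 0], ij[:, 1]


FULL_MASK = RegionMask(frozenset((i, j) for i in range(1, 8) for j in range(1, 8)),
                       "full")
POLE_MASK = RegionMask(frozenset((i, j) for i in (1, 7) for j in range(1, 8)),
                       "pole")
EQUATOR_MASK = RegionMask(frozenset((4, j) for j in range(1, 8)), "equator")


@dataclass
class SummaryStats:
    median: float
    q1: float
    q3: float
    mean: float
    sd: float


@dataclass
class ComparisonReport:
    """Per-case 2D-vs-3D comparison results."""

    r_full: float
    r_by_region: dict = field(default_factory=dict)
    max_density_distance_spacings: float = float("nan")
    max_density_distance_mm: float = float("nan")
    n_tips_2d: int = 0
    n_tips_3d: int = 0
    p_values: dict = field(default_factory=dict)


def density_correlation(
    d2: TipDensityMatrix | np.ndarray,
    d3: TipDensityMatrix | np.ndarray,
    mask: RegionMask = FULL_MASK,
) -> float:
    """Pearson correlation between the two density matrices over the
    masked entries:

        r = sum((D2 - m2)(D3 - m3)) / sqrt(sum((D2-m2)^2) sum((D3-m3)^2))

    with the means m2, m3 taken over the masked entries only.  Zero
    variance in either masked matrix is an error, not a silent 0.
    """
    a = d2.matrix if isinstance(d2, TipDensityMatrix) else np.asarray(d2, float)
    b = d3.matrix if isinstance(d3, TipDensityMatrix) else np.asarray(d3, float)
    if a.shape != (7, 7) or b.shape != (7, 7):
        raise UsageError("density matrices must be 7x7")
    ii, jj = mask.indices()
    x = a[ii, jj] - a[ii, jj].mean()
    y = b[ii, jj] - b[ii, jj].mean()
    sx, sy = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError(
            f"zero variance in masked density ({mask.label}); correlation undefined"
        )
    return float((x * y).sum() / (sx * sy))


def region_masks(
    curv: CurvatureField | None,
    basket: BasketMesh | None,
    k: int = 7,
) -> dict[str, RegionMask]:
    """Standard region masks.

    ``pole`` is rows i in {1, 7} (14 entries), ``equator`` row i=4
    (7 entries).  Given a curvature field on the refined basket mesh,
    ``max_mean_curv``/``min_mean_curv`` and ``max_gauss_curv``/
    ``min_gauss_curv`` each hold the k matrix entries owning the
    highest-/lowest-curvature reliable vertices (vertex -> ancestral
    level-0 face -> sub-square); ties at rank k are resolved by
    lexicographic (i, j) order.
    """
    masks = {"full": FULL_MASK, "pole": POLE_MASK, "equator": EQUATOR_MASK}
    if curv is None:
        return masks
    if basket is None:
        raise UsageError("curvature masks require the basket mesh")

    regions = [
        basket.region_of_level0_face(int(f)) for f in basket.vertex_ancestor_face
    ]
    for name, values in (("mean_curv", curv.mean), ("gauss_curv", curv.gaussian)):
        for direction in ("max", "min"):
            order = []
            for vi in range(len(values)):
                if not curv.reliable[vi] or regions[vi][0] != "sub":
                    continue
                key = -values[vi] if direction == "max" else values[vi]
                order.append((key, regions[vi][1], regions[vi][2], vi))
            order.sort()
            entries: list[tuple[int, int]] = []
            for _, i, j, _vi in order:
                if (i, j) not in entries:
                    entries.append((i, j))
                if len(entries) == k:
                    break
            masks[f"{direction}_{name}"] = RegionMask(
                frozenset(entries), f"{direction}_{name}"
            )
    return masks


def max_density_distance(
    d2: TipDensityMatrix | np.ndarray,
    d3: TipDensityMatrix | np.ndarray,
    spacing_mm: float | None = None,
) -> float | tuple[float, float]:
    """Euclidean distance (electrode-spacing units) between the density
    maxima of the two matrices; argmax ties break lexicographically by
    (i, j).  With *spacing_mm* given, also returns the distance in mm."""
    a = d2.matrix if isinstance(d2, TipDensityMatrix) else np.asarray(d2, float)
    b = d3.matrix if isinstance(d3, TipDensityMatrix) else np.asarray(d3, float)
    if not a.any() or not b.any():
        raise UndefinedStatisticError("no tips in one of the density matrices")
    i2, j2 = np.unravel_index(int(np.argmax(a)), a.shape)
    i3, j3 = np.unravel_index(int(np.argmax(b)), b.shape)
    dist = float(np.hypot(i2 - i3, j2 - j3))
    if spacing_mm is not None:
        return dist, dist * spacing_mm
    return dist


def transfer_singularities(
    ps: list[PhaseSingularity],
    direction: str,
    basket: BasketMesh,
    grid: GridMesh2D,
) -> tuple[list[PhaseSingularity], int]:
    """Carry singularities between the flat grid and the basket shell.

    ``"3d_to_2d"``: each tip's refined face is expressed in its level-0
    ancestor's barycentric coordinates and mapped to the matching grid
    face; tips in the wraparound column or pole caps have no grid
    counterpart and are excluded (their count is returned).
    ``"2d_to_3d"``: each tip's grid position is located in its grid face
    and the same barycentric weights applied to the matching basket
    level-0 face; the tip's ``face``/``lambdas`` then refer to the basket
    level-0 mesh.  Charge and frame are preserved either way.
    """
    out: list[PhaseSingularity] = []
    excluded = 0
    if direction == "3d_to_2d":
        for tip in ps:
            if tip.region[0] != "sub":
                excluded += 1
                continue
            coord = basket.refined_face_barycentric_in_ancestor(tip.face)
            pos = barycentric_position(grid.mesh, coord)
            out.append(
                PhaseSingularity(
                    frame=tip.frame, time_ms=tip.time_ms, charge=tip.charge,
                    x=float(pos[0]), y=float(pos[1]), region=tip.region,
                    face=coord.face, lambdas=coord.lambdas,
                )
            )
    elif direction == "2d_to_3d":
        for tip in ps:
            coord = grid.locate(np.array([tip.x, tip.y]))
            out.append(
                PhaseSingularity(
                    frame=tip.frame, time_ms=tip.time_ms, charge=tip.charge,
                    x=tip.x, y=tip.y, region=tip.region,
                    face=coord.face, lambdas=coord.lambdas,
                )
            )
    else:
        raise UsageError("direction must be '2d_to_3d' or '3d_to_2d'")
    return out, excluded


def paired_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped.  For n <= 25 the exact null
    distribution of W+ is enumerated by dynamic programming (midranks for
    tied |differences|); above that a tie-corrected normal approximation
    (scipy) is used.  p = 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("paired samples must have equal length")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise UsageError("paired samples contain NaN; drop undefined pairs first")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedStatisticError("all paired differences are zero")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n > 25:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=False)
        return float(res.pvalue)
    # exact: distribution of W+ over all 2^n sign assignments via DP.
    # midranks may be half-integers; double them to work on integers.
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0**n
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def summarize(values: np.ndarray) -> SummaryStats:
    """Median and interquartile range (linear-interpolation quartiles),
    plus mean +- SD."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UsageError("cannot summarize an empty collection")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return SummaryStats(
        median=float(med), q1=float(q1), q3=float(q3),
        mean=float(values.mean()), sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
    )


def compare_densities(
    d2: TipDensityMatrix,
    d3: TipDensityMatrix,
    masks: dict[str, RegionMask] | None = None,
    spacing_mm: float = 5.0,
) -> ComparisonReport:
    """Assemble a per-case comparison report from the two density matrices."""
    masks = masks or {"full": FULL_MASK, "pole": POLE_MASK, "equator": EQUATOR_MASK}
    r_by_region = {}
    for name, mask in masks.items():
        try:
            r_by_region[name] = density_correlation(d2, d3, mask)
        except UndefinedStatisticError:
            r_by_region[name] = float("nan")
    try:
        dist, dist_mm = max_density_distance(d2, d3, spacing_mm=spacing_mm)
    except UndefinedStatisticError:
        dist = dist_mm = float("nan")
    return ComparisonReport(
        r_full=r_by_region.get("full", float("nan")),
        r_by_region=r_by_region,
        max_density_distance_spacings=dist,
        max_density_distance_mm=dist_mm,
        n_tips_2d=int(np.sum(d2.matrix > 0)),
        n_tips_3d=int(np.sum(d3.matrix > 0)),
    )
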
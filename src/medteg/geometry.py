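"""Test-grid geometry for perimetry.

Coordinates are visual-field degrees: x positive rightward (temporal field
of the right eye), y positive superior. Provides the standard 24-2 and 10-2
grid constructors, a bounded Voronoi tessellation (cells clipped to a convex
bounding region), compilation of candidate test locations from Voronoi
vertices, and Sibson (natural-neighbor) area weights obtained by inserting a
candidate into the tessellation and measuring how much area its new cell
"steals" from each existing cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import Polygon


def covers_points(polygon: "Polygon", points) -> np.ndarray:
    """Vectorized boundary-inclusive point-in-polygon test."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return shapely.covers(polygon, shapely.points(pts))

#: Dedup / coincidence tolerance in degrees. Far below perimetric stimulus
#: size (Goldmann III is ~0.43 deg across); prevents degenerate
#: re-tessellation when a candidate nearly coincides with a test point.
EPS_POINT = 0.01

#: Half-extent of the default bounding box: the testable field of a
#: standard perimeter (the 24-2 grid reaches 27 deg nasally). The bound
#: matters because a candidate's cell area is its information "footprint";
#: area beyond the testable field must not earn credit, so the box is the
#: device limit rather than an arbitrarily large region.
DEFAULT_HALF_EXTENT = 30.0


class DegenerateGeometryError(ValueError):
    """Fewer than three points, or all points collinear."""


class CoincidentPointError(ValueError):
    """A candidate lies within ``EPS_POINT`` of an existing test point."""


# ---------------------------------------------------------------------------
# basic containers


@dataclass(frozen=True)
class BoundingRegion:
    """Convex polygon delimiting the testable field."""

    polygon: Polygon

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError("bounding region must have positive area")

    @classmethod
    def box(cls, half_extent: float = DEFAULT_HALF_EXTENT) -> "BoundingRegion":
        h = float(half_extent)
        return cls(Polygon([(-h, -h), (h, -h), (h, h), (-h, h)]))

    @property
    def area(self) -> float:
        return self.polygon.area

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        return covers_points(self.polygon, points)


@dataclass
class TestGrid:
    """Tested locations with, optionally, one threshold PMF per location.

    ``pmfs`` is a (n_points, n_threshold_bins) array aligned row-for-row
    with ``points``; it may be None for purely geometric work.
    """

    __test__ = False  # not a test class, despite the name

    points: np.ndarray
    pmfs: np.ndarray | None = None
    eye: str = "right"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("grid points must be finite")
        if len(self.points) > 1:
            tree = cKDTree(self.points)
            pairs = tree.query_pairs(EPS_POINT)
            if pairs:
                raise CoincidentPointError(
                    f"grid points closer than {EPS_POINT} deg: {sorted(pairs)[:3]}"
                )
        if self.pmfs is not None:
            self.pmfs = np.asarray(self.pmfs, dtype=float)
            if self.pmfs.shape[0] != len(self.points):
                raise ValueError("pmfs must align 1:1 with points")
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")

    @property
    def n(self) -> int:
        return len(self.points)

    def add(self, point, pmf=None) -> "TestGrid":
        """Return a new grid with one appended location (grids grow immutably)."""
        pts = np.vstack([self.points, np.asarray(point, dtype=float).reshape(1, 2)])
        if pmf is not None:
            if self.pmfs is None:
                raise ValueError("cannot add a pmf to a grid without pmfs")
            pmfs = np.vstack([self.pmfs, np.asarray(pmf, dtype=float).reshape(1, -1)])
        else:
            pmfs = None if self.pmfs is None else self.pmfs.copy()
        return TestGrid(pts, pmfs, self.eye)

    def with_pmfs(self, pmfs: np.ndarray) -> "TestGrid":
        return TestGrid(self.points.copy(), np.asarray(pmfs, dtype=float), self.eye)


# ---------------------------------------------------------------------------
# standard grids


def build_24_2_grid(eye: str = "right") -> TestGrid:
    """Standard 24-2 grid: 54 locations on a 6 deg lattice offset 3 deg from
    both meridians, plus the two-point nasal step at 27 deg eccentricity.

    Nasal is negative x for the right eye (temporal field, and the blind
    spot, are at positive x); the left eye is the x-mirror.
    """
    pts = []
    for y in (-21, -15, -9, -3, 3, 9, 15, 21):
        for x in (-27, -21, -15, -9, -3, 3, 9, 15, 21):
            if x == -27:
                # nasal step: only the two paracentral rows extend to 27 deg
                if abs(y) == 3:
                    pts.append((x, y))
                continue
            if np.hypot(x, y) <= 24.0:
                pts.append((x, y))
    pts = np.array(pts, dtype=float)
    if eye == "left":
        pts[:, 0] *= -1.0
    return TestGrid(pts, eye=eye)


def build_10_2_grid(eye: str = "right") -> TestGrid:
    """Standard 10-2 grid: 68 locations on a 2 deg lattice offset 1 deg from
    both meridians, all within 10 deg of fixation."""
    odd = np.arange(-9, 10, 2, dtype=float)
    xx, yy = np.meshgrid(odd, odd)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    keep = np.einsum("ij,ij->i", pts, pts) <= 85.0  # drops (3,9)-type corners
    pts = pts[keep]
    if eye == "left":
        pts = pts.copy()
        pts[:, 0] *= -1.0
    return TestGrid(pts, eye=eye)


# ---------------------------------------------------------------------------
# bounded Voronoi tessellation


def _halfplane(p: np.ndarray, q: np.ndarray, extent: float = 1000.0) -> Polygon:
    """Rectangle covering the half-plane of points nearer to p than to q
    (out to ``extent``, which must exceed the bounding-region diameter)."""
    m = 0.5 * (p + q)
    d = q - p
    d = d / np.linalg.norm(d)
    u = np.array([-d[1], d[0]])
    a = m - extent * u
    b = m + extent * u
    return Polygon([a, b, b - extent * d, a - extent * d])


def voronoi_cell(point, others: np.ndarray, region: Polygon) -> Polygon:
    """Voronoi cell of ``point`` against ``others``, clipped to ``region``.

    Built by intersecting perpendicular-bisector half-planes in order of
    nucleus distance; a nucleus farther than twice the current cell radius
    cannot cut the cell, so the loop terminates early.
    """
    p = np.asarray(point, dtype=float)
    cell = region
    others = np.atleast_2d(others)
    if len(others) == 0:
        return cell
    dist = np.linalg.norm(others - p, axis=1)
    order = np.argsort(dist)
    for j in order:
        verts = np.asarray(cell.exterior.coords)
        radius = np.max(np.linalg.norm(verts - p, axis=1))
        if dist[j] > 2.0 * radius:
            break
        cell = cell.intersection(_halfplane(p, others[j]))
    return cell


@dataclass
class VoronoiModel:
    """Bounded tessellation of a grid: one clipped cell polygon per point.

    ``vertex_is_true[i]`` marks vertices equidistant (within tolerance) to
    three or more nuclei, as opposed to artifacts of boundary clipping.
    ``adjacency[i]`` is the set of natural-neighbor indices of point i.
    """

    points: np.ndarray
    region: BoundingRegion
    cells: list
    areas: np.ndarray
    vertices: np.ndarray
    vertex_is_true: np.ndarray
    adjacency: list = field(default_factory=list)


def _merge_close(points: np.ndarray, tol: float) -> np.ndarray:
    """Cluster points within ``tol`` (single linkage) and return centroids."""
    if len(points) == 0:
        return points.reshape(0, 2)
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol)
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(len(points))])
    out = []
    for r in np.unique(roots):
        out.append(points[roots == r].mean(axis=0))
    return np.array(out)


def bounded_voronoi(grid, region: BoundingRegion | None = None) -> VoronoiModel:
    """Tessellate the grid's points, clipping every cell to ``region``.

    Raises DegenerateGeometryError for fewer than three points or a
    collinear configuration.
    """
    points = grid.points if isinstance(grid, TestGrid) else np.asarray(grid, float)
    region = region or BoundingRegion.box()
    n = len(points)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateGeometryError("points are collinear")
    if not region.contains_points(points).all():
        raise ValueError("bounding region must contain all grid points")

    cells = []
    for i in range(n):
        others = np.delete(points, i, axis=0)
        cells.append(voronoi_cell(points[i], others, region.polygon))
    areas = np.array([c.area for c in cells])

    raw = np.vstack([np.asarray(c.exterior.coords)[:-1] for c in cells])
    vertices = _merge_close(raw, EPS_POINT)
    # a genuine Voronoi vertex is equidistant to its >=3 nearest nuclei
    d = np.linalg.norm(vertices[:, None, :] - points[None, :, :], axis=2)
    dmin = d.min(axis=1)
    ties = (d <= dmin[:, None] + 1e-6).sum(axis=1)
    vertex_is_true = ties >= 3

    try:
        tri = Delaunay(points)
        adjacency = [set() for _ in range(n)]
        for simplex in tri.simplices:
            for a in simplex:
                for b in simplex:
                    if a != b:
                        adjacency[a].add(int(b))
    except QhullError:  # pragma: no cover - rank check above catches this
        adjacency = [set() for _ in range(n)]

    return VoronoiModel(points, region, cells, areas, vertices, vertex_is_true,
                        adjacency)


# ---------------------------------------------------------------------------
# convex hull and candidate compilation


def convex_hull(grid) -> Polygon:
    """Convex hull of the grid's points as a polygon."""
    points = grid.points if isinstance(grid, TestGrid) else np.asarray(grid, float)
    if len(points) < 3:
        raise DegenerateGeometryError("need at least 3 points for a hull")
    from scipy.spatial import ConvexHull

    try:
        ch = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateGeometryError("collinear points have no 2-D hull") from exc
    return Polygon(points[ch.vertices])


@dataclass
class CandidateSet:
    """Deduplicated candidate locations with their provenance.

    ``provenance`` entries are "vertex" (a true Voronoi vertex, equidistant
    to >=3 grid points) or "boundary" (created by clipping cells to the
    bounding region).
    """

    points: np.ndarray
    provenance: list
    hull: Polygon

    def __len__(self) -> int:
        return len(self.points)


def compile_candidates(vor: VoronoiModel, grid: TestGrid,
                       restrict_to_hull: bool = True) -> CandidateSet:
    """Candidate locations = Voronoi vertices of the current grid.

    Vertices within ``EPS_POINT`` of an existing test point are dropped, and
    (optionally) so are vertices outside the grid's convex hull. An empty
    result is returned as an empty CandidateSet, not an error.
    """
    hull = convex_hull(grid)
    pts = vor.vertices
    prov = np.where(vor.vertex_is_true, "vertex", "boundary")
    if len(pts) == 0:
        return CandidateSet(pts.reshape(0, 2), [], hull)
    if restrict_to_hull:
        keep = covers_points(hull.buffer(1e-9), pts)
        pts, prov = pts[keep], prov[keep]
    if len(pts) and len(grid.points):
        d = np.linalg.norm(pts[:, None, :] - grid.points[None, :, :], axis=2)
        keep = d.min(axis=1) >= EPS_POINT
        pts, prov = pts[keep], prov[keep]
    return CandidateSet(pts, list(prov), hull)


# ---------------------------------------------------------------------------
# Sibson (natural-neighbor) weights


@dataclass
class SibsonWeights:
    """Natural-neighbor weights of a candidate inserted into a grid.

    ``cell_area`` is the candidate's new Voronoi cell area A_c;
    ``intersection_areas[i]`` is the area that cell steals from neighbor
    ``neighbor_idx[i]``'s original cell; weights are the normalized stolen
    areas (nonnegative, summing to 1).
    """

    neighbor_idx: np.ndarray
    weights: np.ndarray
    cell_area: float
    intersection_areas: np.ndarray
    cell: Polygon | None = None


def sibson_weights(candidate, grid, region: BoundingRegion | None = None,
                   vor: VoronoiModel | None = None,
                   hemifield_mask: bool = False,
                   vertical_mask: bool = False) -> SibsonWeights:
    """Insert ``candidate`` into the tessellation and weight each existing
    point by the area its cell cedes to the candidate's new cell.

    With ``hemifield_mask`` (``vertical_mask``), an off-meridian candidate
    draws only on neighbors within its own hemifield — zeroing, before
    renormalization, the weights of neighbors across (or on) the horizontal
    (vertical) meridian — mirroring the anatomical fact that nerve-fiber
    bundles terminate at the raphe and do not cross it. If no strictly
    same-side neighbor exists, on-meridian neighbors are readmitted; a
    candidate exactly on the meridian uses all neighbors.
    """
    cand = np.asarray(candidate, dtype=float).reshape(2)
    points = grid.points if isinstance(grid, TestGrid) else np.asarray(grid, float)
    region = region or (vor.region if vor is not None else BoundingRegion.box())
    d = np.linalg.norm(points - cand, axis=1)
    if d.min() < EPS_POINT:
        raise CoincidentPointError(
            f"candidate {tuple(cand)} coincides with grid point {int(d.argmin())}")
    if vor is None:
        vor = bounded_voronoi(points, region)

    cell = voronoi_cell(cand, points, region.polygon)
    a_c = cell.area
    minx, miny, maxx, maxy = cell.bounds
    idx, areas = [], []
    for i, old in enumerate(vor.cells):
        ox0, oy0, ox1, oy1 = old.bounds
        if ox1 < minx or ox0 > maxx or oy1 < miny or oy0 > maxy:
            continue
        a = cell.intersection(old).area
        if a > 1e-12 * max(a_c, 1.0):
            idx.append(i)
            areas.append(a)
    idx = np.array(idx, dtype=int)
    areas = np.array(areas, dtype=float)

    def axis_mask(axis: int) -> np.ndarray:
        side = points[idx, axis] * cand[axis]
        strict = side > 0
        return strict if strict.any() else side >= 0

    mask = np.ones(len(idx), dtype=bool)
    if hemifield_mask and cand[1] != 0:
        mask &= axis_mask(1)
    if vertical_mask and cand[0] != 0:
        mask &= axis_mask(0)
    if not mask.any():
        mask[:] = True  # degenerate: keep the unmasked neighborhood
    idx, areas = idx[mask], areas[mask]
    return SibsonWeights(idx, areas / areas.sum(), a_c, areas, cell)
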
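"""The MEDTEG scoring and selection pipeline.

For the current grid, candidate locations are the Voronoi vertices of the
tessellation. Each candidate c is scored as

    score(c) = omega(c) * E(dH | c) * A_c

where the candidate's threshold PMF is the Sibson (natural-neighbor)
weighted sum of its neighbors' PMFs, E(dH) is the one-trial-ahead expected
entropy reduction under that PMF, A_c is the area of the candidate's
would-be Voronoi cell (so information is valued per unit of field covered),
and omega in [0, 1] encodes user preferences (device limits, meridian or
blind-spot exclusion, structural priors...). The candidate maximizing the
score is the recommended next test location. An "H-max" variant scores by
current entropy H instead of E(dH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from . import bayes, geometry
from .bayes import PsychometricParams
from .geometry import BoundingRegion, SibsonWeights, TestGrid, VoronoiModel


class NoCandidateError(RuntimeError):
    """No candidate with positive weight is available."""


# ---------------------------------------------------------------------------
# per-candidate weight rules: callables mapping (n, 2) points -> [0, 1]


def inside_hull(hull: Polygon):
    """Zero weight outside the (buffered) convex hull of the original grid."""
    slack = hull.buffer(1e-9)

    def rule(points):
        return geometry.covers_points(slack, points).astype(float)

    return rule


def meridian_exclusion(half_width: float = 1.0, axis: str = "horizontal"):
    """Zero weight within ``half_width`` deg of the horizontal (or vertical)
    meridian, where nerve-fiber anatomy makes thresholds discontinuous."""
    k = 1 if axis == "horizontal" else 0

    def rule(points):
        pts = np.atleast_2d(points)
        return (np.abs(pts[:, k]) >= half_width).astype(float)

    return rule


def blind_spot_exclusion(center=(15.0, -1.5), radius: float = 2.5):
    def rule(points):
        pts = np.atleast_2d(points)
        d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        return (d > radius).astype(float)

    return rule


def device_range(polygon: Polygon):
    """Zero weight outside the stimulus-presentable range of the device."""

    def rule(points):
        return geometry.covers_points(polygon, points).astype(float)

    return rule


def eccentricity_decay(d0: float = 10.0):
    """Gradated central preference: omega = 1 / (1 + ecc / d0), a bounded
    stand-in for 'inversely proportional to distance from fixation'."""

    def rule(points):
        pts = np.atleast_2d(points)
        return 1.0 / (1.0 + np.hypot(pts[:, 0], pts[:, 1]) / d0)

    return rule


def structural_weight(smap):
    """Weights from a gridded structural map (bilinear lookup)."""
    return lambda points: smap.value(points)


def combined_weight(points, rules) -> np.ndarray:
    """Product of all rule outputs, clamped to [0, 1]; empty list gives 1."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.ones(len(pts))
    for rule in rules:
        w = w * np.clip(np.asarray(rule(pts), dtype=float), 0.0, 1.0)
    return np.clip(w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# configuration and scoring


@dataclass
class MedtegConfig:
    """Everything MEDTEG needs beyond the grid itself.

    ``sigma_field``, if given, maps (n, 2) points to per-location
    psychometric spreads (overriding ``params.sigma``), letting the score
    prefer regions where responses are more reliable.
    """

    mode: str = "edh"  # "edh" | "hmax"
    restrict_to_hull: bool = True
    hemifield_mask: bool = False
    weight_rules: tuple = ()
    selection: str = "argmax"  # "argmax" | "top_n" | "stochastic"
    top_n: int = 1
    params: PsychometricParams = field(default_factory=PsychometricParams)
    sigma_field: callable | None = None
    stim_domain: np.ndarray = field(default_factory=bayes.default_stimulus_domain)
    thresh_domain: np.ndarray = field(default_factory=bayes.default_threshold_domain)
    region: BoundingRegion = field(default_factory=BoundingRegion.box)
    trials_per_location: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("edh", "hmax"):
            raise ValueError("mode must be 'edh' or 'hmax'")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    def params_at(self, point) -> PsychometricParams:
        if self.sigma_field is None:
            return self.params
        s = float(np.asarray(self.sigma_field(np.atleast_2d(point))).ravel()[0])
        return self.params.with_sigma(s)


@dataclass
class CandidateScore:
    """Full scoring record for one candidate location."""

    point: np.ndarray
    pmf: np.ndarray
    H: float
    e_dh: float | None
    cell_area: float
    omega: float
    sibson: SibsonWeights

    @property
    def info(self) -> float:
        """The information term used by the active mode (E(dH), or H)."""
        return self.H if self.e_dh is None else self.e_dh

    @property
    def score_deg2(self) -> float:
        """Information volume: info (bits) times cell area (deg^2)."""
        return self.info * self.cell_area

    @property
    def final_score(self) -> float:
        return self.score_deg2 * self.omega


def interpolate_pmf(candidate, grid: TestGrid, sibson: SibsonWeights) -> np.ndarray:
    """Candidate PMF as the Sibson-weighted sum of neighbor PMFs."""
    if grid.pmfs is None:
        raise ValueError("grid has no PMFs to interpolate")
    if abs(sibson.weights.sum() - 1.0) > 1e-9:
        raise ValueError("Sibson weights must sum to 1")
    return sibson.weights @ grid.pmfs[sibson.neighbor_idx]


def score_candidates(grid: TestGrid, config: MedtegConfig,
                     vor: VoronoiModel | None = None) -> list[CandidateScore]:
    """Compile and score all candidates with positive weight.

    Zero-weight candidates are discarded before any Bayesian work — they can
    never be selected. Returns an empty list when nothing scoreable remains.
    """
    if grid.pmfs is None or grid.n < 3:
        raise ValueError("need a grid with >=3 points carrying PMFs")
    vor = vor or geometry.bounded_voronoi(grid, config.region)
    cands = geometry.compile_candidates(vor, grid, config.restrict_to_hull)
    if len(cands) == 0:
        return []
    omegas = combined_weight(cands.points, config.weight_rules)
    scores: list[CandidateScore] = []
    for pt, om in zip(cands.points, omegas):
        if om <= 0.0:
            continue
        sw = geometry.sibson_weights(pt, grid, config.region, vor=vor,
                                     hemifield_mask=config.hemifield_mask)
        pmf = interpolate_pmf(pt, grid, sw)
        h = bayes.entropy(pmf)
        if config.mode == "edh":
            e_dh, _ = bayes.expected_entropy_reduction(
                pmf, config.stim_domain, config.thresh_domain,
                config.params_at(pt))
        else:
            e_dh = None
        # area credit: a candidate only earns information volume over the
        # field the test is characterizing, so when candidates are confined
        # to the grid's hull, so is the credited cell area (otherwise cells
        # on the rim sweep up unbounded outside area and dominate).
        area = sw.cell_area
        if config.restrict_to_hull and sw.cell is not None:
            area = sw.cell.intersection(cands.hull).area
        scores.append(CandidateScore(pt, pmf, h, e_dh, area, om, sw))
    return scores


def _ordering(scores) -> np.ndarray:
    """Indices sorted by descending final score, ties broken by proximity to
    fixation and then by list order (deterministic)."""
    final = np.array([s.final_score for s in scores])
    ecc = np.array([np.hypot(*s.point) for s in scores])
    idx = np.arange(len(scores))
    return np.lexsort((idx, ecc, -final))


def select_next(scores, config: MedtegConfig,
                rng: np.random.Generator | None = None):
    """Pick the winning candidate(s) from a scored list.

    argmax returns the single best CandidateScore; top_n returns the best N
    from this one scoring pass; stochastic samples one with probability
    proportional to final score (uniform if all scores are zero).
    """
    if not scores:
        raise NoCandidateError("no scored candidates to select from")
    order = _ordering(scores)
    if config.selection == "top_n":
        return [scores[i] for i in order[: config.top_n]]
    if config.selection == "stochastic":
        if rng is None:
            raise ValueError("stochastic selection needs an rng")
        final = np.array([s.final_score for s in scores])
        total = final.sum()
        p = final / total if total > 0 else np.full(len(scores), 1 / len(scores))
        return scores[int(rng.choice(len(scores), p=p))]
    return scores[order[0]]


def medteg_selector(grid: TestGrid, config: MedtegConfig,
                    rng: np.random.Generator | None = None) -> CandidateScore:
    """Score the grid and return MEDTEG's recommended next location."""
    scores = score_candidates(grid, config)
    if not scores:
        raise NoCandidateError("all candidates have zero weight")
    return select_next(scores, config, rng)


def grow_grid(grid: TestGrid, hov, n_new: int, config: MedtegConfig,
              rng: np.random.Generator, selector=None) -> TestGrid:
    """Recursively add ``n_new`` locations to the grid.

    Each round: score candidates, select one, run a fixed number of
    entropy-optimal trials against the simulated observer ``hov`` starting
    from the candidate's interpolated PMF, then append the location with its
    posterior and re-tessellate. ``selector`` defaults to MEDTEG's and may
    be swapped for a baseline policy with the same signature.
    """
    from .observer import respond  # local import avoids a cycle

    selector = selector or medteg_selector
    g = grid
    for _ in range(int(n_new)):
        chosen = selector(g, config, rng)
        loc = chosen.point
        params = config.params_at(loc)
        posterior, _ = bayes.run_trials(
            chosen.pmf, lambda s: respond(hov, loc, s, config.params, rng),
            config.trials_per_location, params, config.stim_domain,
            config.thresh_domain, location=loc)
        g = g.add(loc, posterior)
    return g
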
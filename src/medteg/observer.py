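"""Synthetic perimetric observers.

A simulated observer is a "hill of vision": a true sensitivity surface
mu(x, y) in dB and a psychometric-slope surface sigma(x, y), plus a
physiologic blind spot. Responses to stimuli are Bernoulli draws from the
frequency-of-seeing curve evaluated at the true surface values.

The normative surface is a simple parametric stand-in for a normally
sighted young adult (it is not a published normative model): a foveal peak
declining with eccentricity, with smooth seeded spatial jitter so that no
two observers — and no two locations — are exactly alike.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Polygon

from .bayes import PsychometricParams, p_seen

MU_CEILING = 40.0


def _as_points(points) -> np.ndarray:
    return np.asarray(points, dtype=float).reshape(-1, 2)


class SmoothJitterField:
    """Smooth zero-mean Gaussian random field with unit variance, built from
    random cosine features (squared-exponential-like covariance). Evaluation
    is deterministic given the seed and smooth in space, so jitter behaves
    like stable anatomical idiosyncrasy rather than per-call noise."""

    def __init__(self, rng: np.random.Generator, length_scale: float = 6.0,
                 n_features: int = 64):
        self.freqs = rng.normal(scale=1.0 / length_scale, size=(n_features, 2))
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
        self.scale = np.sqrt(2.0 / n_features)

    def __call__(self, points) -> np.ndarray:
        pts = _as_points(points)
        return self.scale * np.cos(pts @ self.freqs.T + self.phases).sum(axis=1)


# ---------------------------------------------------------------------------
# field defects


@dataclass(frozen=True)
class CentralScotoma:
    """Localized loss: discs of ``radius`` around ``centers``, depressed by
    ``depths`` dB (overlapping discs take the deepest loss, not the sum)."""

    centers: tuple
    depths: tuple
    radius: float = 3.0

    def apply(self, points: np.ndarray, mu: np.ndarray) -> np.ndarray:
        pts = _as_points(points)
        drop = np.zeros(len(pts))
        for (cx, cy), depth in zip(self.centers, self.depths):
            inside = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= self.radius
            drop = np.where(inside, np.maximum(drop, depth), drop)
        return mu - drop


@dataclass(frozen=True)
class HemifieldLoss:
    """Total loss in one hemifield: mu is floored to 0 and, because the
    loss is complete ("no measurable sensitivity"), the observer responds
    at the guess rate there — like the blind spot — rather than half-seeing
    the brightest stimuli as a threshold of 0 dB would imply."""

    side: str = "superior"  # superior | inferior | left | right
    absolute: bool = True

    def covers(self, points: np.ndarray) -> np.ndarray:
        pts = _as_points(points)
        if self.side == "superior":
            return pts[:, 1] > 0
        if self.side == "inferior":
            return pts[:, 1] < 0
        if self.side == "right":
            return pts[:, 0] > 0
        if self.side == "left":
            return pts[:, 0] < 0
        raise ValueError(f"unknown hemifield {self.side!r}")

    def apply(self, points: np.ndarray, mu: np.ndarray) -> np.ndarray:
        return np.where(self.covers(points), 0.0, mu)


@dataclass(frozen=True)
class RegionalLoss:
    """Uniform loss of ``depth`` dB inside a polygonal region."""

    polygon: Polygon
    depth: float

    def covers(self, points: np.ndarray) -> np.ndarray:
        from .geometry import covers_points

        return covers_points(self.polygon, _as_points(points))

    def apply(self, points: np.ndarray, mu: np.ndarray) -> np.ndarray:
        return np.where(self.covers(points), mu - self.depth, mu)


# ---------------------------------------------------------------------------
# the hill of vision


@dataclass
class HillOfVision:
    """Ground-truth sensitivity and slope surfaces for one simulated eye."""

    mu_base: callable
    sigma_base: callable
    defects: tuple = ()
    blind_spot_center: tuple = (15.0, -1.5)
    blind_spot_radius: float = 2.5
    eye: str = "right"

    def in_blind_spot(self, points) -> np.ndarray:
        pts = _as_points(points)
        cx, cy = self.blind_spot_center
        return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= self.blind_spot_radius

    def mu(self, points) -> np.ndarray:
        """True DLS surface: base minus defects, 0 in the blind spot,
        clamped to [0, 40] dB."""
        pts = _as_points(points)
        m = np.asarray(self.mu_base(pts), dtype=float)
        for defect in self.defects:
            m = defect.apply(pts, m)
        m = np.where(self.in_blind_spot(pts), 0.0, m)
        return np.clip(m, 0.0, MU_CEILING)

    def sigma(self, points) -> np.ndarray:
        return np.asarray(self.sigma_base(_as_points(points)), dtype=float)

    def is_nonseeing(self, points) -> np.ndarray:
        """True where the observer cannot respond above guess rate: the
        blind spot plus any region of absolute loss."""
        pts = _as_points(points)
        blind = self.in_blind_spot(pts)
        for defect in self.defects:
            if getattr(defect, "absolute", False):
                blind = blind | defect.covers(pts)
        return blind

    def mu_at(self, point) -> float:
        return float(self.mu(point)[0])

    def sigma_at(self, point) -> float:
        return float(self.sigma(point)[0])


def normative_mean(points, peak: float = 33.0, lin: float = 0.08,
                   quad: float = 0.0006) -> np.ndarray:
    """Expected normal sensitivity (dB) at each location: the jitter-free
    population hill of vision an examiner would assume a priori."""
    pts = _as_points(points)
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    return peak - lin * ecc - quad * ecc**2


def normative_observer(seed=0, peak: float = 33.0, lin: float = 0.08,
                       quad: float = 0.0006, mu_jitter_sd: float = 1.0,
                       sigma0: float = 1.5, sigma_jitter_sd: float = 0.25,
                       sigma_floor: float = 0.5, eye: str = "right",
                       rng: np.random.Generator | None = None) -> HillOfVision:
    """Parametric normal hill of vision with seeded smooth jitter.

    mu(x, y) = peak - lin * ecc - quad * ecc^2 (about 30 dB at 27 deg
    eccentricity) plus a smooth jitter field of s.d. ``mu_jitter_sd``;
    sigma(x, y) = sigma0 plus jitter of s.d. ``sigma_jitter_sd``, floored.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    mu_jit = SmoothJitterField(rng)
    sg_jit = SmoothJitterField(rng)

    def mu_base(pts):
        return normative_mean(pts, peak, lin, quad) + mu_jitter_sd * mu_jit(pts)

    def sigma_base(pts):
        return np.maximum(sigma0 + sigma_jitter_sd * sg_jit(pts), sigma_floor)

    bs_x = 15.0 if eye == "right" else -15.0
    return HillOfVision(mu_base, sigma_base, (), (bs_x, -1.5), 2.5, eye)


def apply_defects(hov: HillOfVision, defects) -> HillOfVision:
    """Return a new observer with ``defects`` appended (composable)."""
    return replace(hov, defects=tuple(hov.defects) + tuple(defects))


def respond(hov: HillOfVision, location, stimulus: float,
            params: PsychometricParams, rng: np.random.Generator) -> bool:
    """One stochastic trial: Bernoulli draw from the frequency-of-seeing
    curve at the observer's true mu and sigma. Inside the blind spot, or a
    region of absolute loss, the seen-probability is the guess rate."""
    loc = np.asarray(location, dtype=float).reshape(2)
    if bool(hov.is_nonseeing(loc)[0]):
        p = params.guess
    else:
        true_params = params.with_sigma(hov.sigma_at(loc))
        p = p_seen(float(stimulus), hov.mu_at(loc), true_params)
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# structural weight maps


@dataclass
class StructuralMap:
    """Gridded candidate-weight field in [0.01, 1], e.g. derived from OCT.

    ``values`` has shape (len(y), len(x)); lookups are bilinear with edge
    clamping, and outputs are always clamped back into [0.01, 1].
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.clip(np.asarray(self.values, dtype=float), 0.01, 1.0)
        if self.values.shape != (len(self.y), len(self.x)):
            raise ValueError("values must have shape (len(y), len(x))")
        self._interp = RegularGridInterpolator(
            (self.y, self.x), self.values, bounds_error=False, fill_value=None)

    def value(self, points) -> np.ndarray:
        pts = _as_points(points)
        q = np.column_stack([
            np.clip(pts[:, 1], self.y[0], self.y[-1]),
            np.clip(pts[:, 0], self.x[0], self.x[-1]),
        ])
        return np.clip(self._interp(q), 0.01, 1.0)

    def with_noise(self, rng: np.random.Generator, sd: float = 1.0) -> "StructuralMap":
        """Jitter every lattice weight by N(0, sd), clamped to [0.01, 1]."""
        noisy = self.values + rng.normal(0.0, sd, size=self.values.shape)
        return StructuralMap(self.x, self.y, noisy)

    def x_flipped(self) -> "StructuralMap":
        """Mirror the map about the vertical meridian (an involution)."""
        return StructuralMap(-self.x[::-1], self.y, self.values[:, ::-1])


def structural_map_from_region(polygon: Polygon, inside: float = 1.0,
                               outside: float = 0.01, spacing: float = 2.0,
                               extent: float = 29.0) -> StructuralMap:
    """Binary-valued structural map: ``inside`` weight on lattice points
    covered by ``polygon``, ``outside`` elsewhere."""
    from .geometry import covers_points

    ax = np.arange(-extent, extent + spacing / 2, spacing)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mask = covers_points(polygon, pts).reshape(xx.shape)
    vals = np.where(mask, inside, outside)
    return StructuralMap(ax, ax, vals)
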
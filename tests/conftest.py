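import numpy as np
import pytest

from medteg import BoundingRegion, TestGrid
from medteg import bayes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square_grid():
    """2x2 unit square of points with a concentric bounding box."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    region = BoundingRegion.box(2.0)
    return TestGrid(pts - 0.5), region


def random_grid(rng, n, extent=20.0, min_sep=1.0):
    """Random well-separated point set inside +/- extent."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(-extent, extent, 2)
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def mc_cell_areas(points, region, rng, n_samples=200_000):
    """Monte-Carlo nearest-nucleus estimate of bounded Voronoi cell areas."""
    minx, miny, maxx, maxy = region.polygon.bounds
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    samples = np.column_stack([xs, ys])
    d = np.linalg.norm(samples[:, None, :] - points[None, :, :], axis=2)
    owner = d.argmin(axis=1)
    box_area = (maxx - minx) * (maxy - miny)
    return np.bincount(owner, minlength=len(points)) / n_samples * box_area


def brute_force_edh(prior, stim_domain, thresh_domain, params):
    """Naive triple loop over stimuli, responses and thresholds."""
    prior = np.asarray(prior, float)
    h_prior = -sum(p * np.log2(p) for p in prior if p > 0)
    best = None
    for stim in stim_domain:
        exp_h = 0.0
        for seen in (True, False):
            joint = np.array([
                prior[m] * (bayes.p_seen(stim, mu, params) if seen
                            else 1 - bayes.p_seen(stim, mu, params))
                for m, mu in enumerate(thresh_domain)])
            p_r = joint.sum()
            if p_r == 0:
                continue
            post = joint / p_r
            h = -sum(p * np.log2(p) for p in post if p > 0)
            exp_h += p_r * h
        if best is None or exp_h < best[0] - 1e-15:
            best = (exp_h, stim)
    return max(h_prior - best[0], 0.0), best[1]
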
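import numpy as np
import pytest

from medteg import (MedtegConfig, NoCandidateError,
                    PsychometricParams, TestGrid, bounded_voronoi,
                    combined_weight, convex_hull, entropy, grow_grid,
                    interpolate_pmf, score_candidates, select_next,
                    sibson_weights)
from medteg import bayes, core
from medteg.core import CandidateScore, medteg_selector
from medteg.observer import normative_observer

from conftest import brute_force_edh, random_grid


def point_mass(n, k):
    p = np.zeros(n)
    p[k] = 1.0
    return p


def make_grid_with_pmfs(points, pmfs):
    return TestGrid(np.asarray(points, float), np.asarray(pmfs, float))


SQUARE = np.array([[-6.0, -6.0], [6.0, -6.0], [6.0, 6.0], [-6.0, 6.0]])


class TestInterpolatePmf:
    def test_identical_neighbors_reproduce_pmf(self, rng):
        q = rng.random(41)
        q /= q.sum()
        grid = make_grid_with_pmfs(SQUARE, np.tile(q, (4, 1)))
        sw = sibson_weights([0.0, 0.0], grid)
        assert np.allclose(interpolate_pmf([0.0, 0.0], grid, sw), q)

    def test_divergent_point_masses_give_one_bit(self):
        pmfs = [point_mass(41, 10), point_mass(41, 30),
                point_mass(41, 10), point_mass(41, 30)]
        grid = make_grid_with_pmfs(SQUARE, pmfs)
        sw = sibson_weights([0.0, 0.0], grid)
        pmf = interpolate_pmf([0.0, 0.0], grid, sw)
        assert pmf[10] == pytest.approx(0.5)
        assert pmf[30] == pytest.approx(0.5)
        assert entropy(pmf) == pytest.approx(1.0)

    def test_matches_manual_weighted_sum(self, rng):
        pts = random_grid(rng, 7)
        pmfs = rng.random((7, 21))
        pmfs /= pmfs.sum(axis=1, keepdims=True)
        grid = make_grid_with_pmfs(pts, pmfs)
        cand = pts.mean(axis=0)
        sw = sibson_weights(cand, grid)
        manual = np.zeros(21)
        for w, i in zip(sw.weights, sw.neighbor_idx):
            manual += w * pmfs[i]
        assert np.allclose(interpolate_pmf(cand, grid, sw), manual, atol=1e-12)


class TestWeightRules:
    def test_empty_rule_list_gives_one(self):
        assert combined_weight([[3.0, 4.0]], []) == pytest.approx(1.0)

    def test_meridian_exclusion(self):
        rule = core.meridian_exclusion(1.0)
        w = combined_weight([[5.0, 0.5], [5.0, 1.5]], [rule])
        assert list(w) == [0.0, 1.0]

    def test_inside_hull_rule(self):
        hull = convex_hull(SQUARE)
        rule = core.inside_hull(hull)
        w = combined_weight([[0.0, 0.0], [10.0, 0.0]], [rule])
        assert list(w) == [1.0, 0.0]

    def test_rules_multiply_and_clamp(self):
        half = lambda pts: np.full(len(np.atleast_2d(pts)), 0.5)
        w = combined_weight([[0.0, 0.0]], [half, half])
        assert w[0] == pytest.approx(0.25)
        big = lambda pts: np.full(len(np.atleast_2d(pts)), 3.0)
        assert combined_weight([[0.0, 0.0]], [big])[0] == 1.0

    def test_eccentricity_decay_prefers_center(self):
        rule = core.eccentricity_decay(10.0)
        w = combined_weight([[0.0, 0.0], [0.0, 10.0], [0.0, 30.0]], [rule])
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.5)
        assert np.all(np.diff(w) < 0)

    def test_blind_spot_exclusion(self):
        rule = core.blind_spot_exclusion((15.0, -1.5), 2.5)
        w = combined_weight([[15.0, -1.5], [15.0, -6.0]], [rule])
        assert list(w) == [0.0, 1.0]


class TestScoreCandidates:
    def cross_grid(self, rng):
        pts = np.array([[-6.0, 0.0], [6.0, 0.0], [0.0, 6.0], [0.0, -6.0],
                        [0.0, 0.0]])
        pmfs = rng.random((5, 41))
        pmfs /= pmfs.sum(axis=1, keepdims=True)
        return make_grid_with_pmfs(pts, pmfs)

    def test_zero_weight_candidates_are_discarded(self, rng):
        grid = self.cross_grid(rng)
        cfg = MedtegConfig(weight_rules=(lambda pts: np.zeros(len(np.atleast_2d(pts))),))
        assert score_candidates(grid, cfg) == []

    def test_scores_compose_area_weight_and_information(self, rng):
        grid = self.cross_grid(rng)
        cfg = MedtegConfig()
        scores = score_candidates(grid, cfg)
        assert scores
        for s in scores:
            assert s.final_score == pytest.approx(s.e_dh * s.cell_area * s.omega)
            assert s.final_score >= 0
            assert s.H >= 0

    def test_pipeline_matches_composed_oracle(self, rng):
        """Five-point toy grid: every scored quantity is rebuilt from the
        independent pieces (Sibson weights, manual mixture, brute-force
        expected entropy reduction, clipped polygon area)."""
        grid = self.cross_grid(rng)
        cfg = MedtegConfig(params=PsychometricParams(2.0, 0.05, 0.02))
        scores = score_candidates(grid, cfg)
        hull = convex_hull(grid)
        for s in scores[:3]:
            sw = sibson_weights(s.point, grid, cfg.region)
            manual_pmf = sum(w * grid.pmfs[i]
                             for w, i in zip(sw.weights, sw.neighbor_idx))
            assert np.allclose(s.pmf, manual_pmf, atol=1e-12)
            e_dh, _ = brute_force_edh(manual_pmf, cfg.stim_domain,
                                      cfg.thresh_domain, cfg.params)
            assert s.e_dh == pytest.approx(e_dh, abs=1e-9)
            assert s.cell_area == pytest.approx(
                sw.cell.intersection(hull).area, abs=1e-9)

    def test_area_monotonicity_of_final_score(self, rng):
        pmf = np.full(41, 1 / 41)
        sw = None
        small = CandidateScore(np.zeros(2), pmf, 1.0, 0.5, 10.0, 1.0, sw)
        large = CandidateScore(np.zeros(2), pmf, 1.0, 0.5, 20.0, 1.0, sw)
        assert large.final_score > small.final_score

    def test_divergent_neighborhoods_promise_more_information(self):
        """The entropy-ordering property: a candidate whose neighbors
        disagree (bimodal mixture) has at least the expected gain of one
        whose neighbors agree, all else equal."""
        dom = np.arange(0.0, 41.0)
        params = PsychometricParams(1.5, 0.05, 0.02)
        agree = 0.5 * _gauss(dom, 25, 2) + 0.5 * _gauss(dom, 27, 2)
        diverge = 0.5 * _gauss(dom, 10, 2) + 0.5 * _gauss(dom, 30, 2)
        assert entropy(diverge) > entropy(agree)
        e_agree, _ = bayes.expected_entropy_reduction(agree, dom, dom, params)
        e_div, _ = bayes.expected_entropy_reduction(diverge, dom, dom, params)
        assert e_div >= e_agree

    def test_hmax_mode_scores_by_entropy(self, rng):
        grid = self.cross_grid(rng)
        scores = score_candidates(grid, MedtegConfig(mode="hmax"))
        for s in scores:
            assert s.e_dh is None
            assert s.final_score == pytest.approx(s.H * s.cell_area * s.omega)

    def test_hmax_and_edh_agree_on_unambiguous_case(self):
        """With a constant slope and one candidate whose neighborhood is
        clearly most uncertain, both variants pick the same location."""
        pts = np.array([[-12.0, 0.0], [0.0, 12.0], [12.0, 0.0], [0.0, -12.0],
                        [-6.0, -6.0], [6.0, 6.0]])
        dom = np.arange(0.0, 41.0)
        pmfs = np.tile(_gauss(dom, 30, 1.5), (6, 1))
        pmfs[0] = _gauss(dom, 5, 1.5)  # one deviant location
        grid = make_grid_with_pmfs(pts, pmfs)
        picks = {}
        for mode in ("edh", "hmax"):
            s = medteg_selector(grid, MedtegConfig(mode=mode))
            picks[mode] = tuple(np.round(s.point, 6))
        assert picks["edh"] == picks["hmax"]


def _gauss(dom, mu, sd):
    p = np.exp(-0.5 * ((dom - mu) / sd) ** 2)
    return p / p.sum()


class TestSelectNext:
    def fake_scores(self, finals):
        pmf = np.full(41, 1 / 41)
        return [CandidateScore(np.array([i + 1.0, 0.0]), pmf, 1.0, f, 1.0,
                               1.0, None)
                for i, f in enumerate(finals)]

    def test_single_candidate_returned(self):
        s = self.fake_scores([2.0])
        assert select_next(s, MedtegConfig()) is s[0]

    def test_argmax_picks_highest(self):
        s = self.fake_scores([3.0, 1.0, 2.0])
        assert select_next(s, MedtegConfig()) is s[0]

    def test_tie_breaks_toward_fixation(self):
        pmf = np.full(41, 1 / 41)
        far = CandidateScore(np.array([10.0, 0.0]), pmf, 1.0, 1.0, 1.0, 1.0, None)
        near = CandidateScore(np.array([2.0, 0.0]), pmf, 1.0, 1.0, 1.0, 1.0, None)
        assert select_next([far, near], MedtegConfig()) is near

    def test_empty_scores_raise(self):
        with pytest.raises(NoCandidateError):
            select_next([], MedtegConfig())

    def test_top_n_returns_best_without_replacement(self):
        s = self.fake_scores([1.0, 4.0, 3.0, 2.0])
        top = select_next(s, MedtegConfig(selection="top_n", top_n=2))
        assert top == [s[1], s[2]]

    def test_stochastic_frequencies_proportional_to_score(self, rng):
        s = self.fake_scores([1.0, 1.0])
        cfg = MedtegConfig(selection="stochastic")
        n = 10_000
        picks = sum(select_next(s, cfg, rng) is s[0] for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(picks / n - 0.5) < 3 * se

    def test_zero_weight_candidate_never_selected_stochastically(self, rng):
        pmf = np.full(41, 1 / 41)
        zero = CandidateScore(np.array([1.0, 0.0]), pmf, 1.0, 1.0, 1.0, 0.0, None)
        live = CandidateScore(np.array([9.0, 0.0]), pmf, 1.0, 1.0, 1.0, 1.0, None)
        cfg = MedtegConfig(selection="stochastic")
        for _ in range(200):
            assert select_next([zero, live], cfg, rng) is live


class TestGrowGrid:
    def test_zero_additions_returns_grid_unchanged(self, rng):
        pts = random_grid(rng, 5)
        pmfs = np.tile(np.full(41, 1 / 41), (5, 1))
        grid = make_grid_with_pmfs(pts, pmfs)
        hov = normative_observer(0)
        out = grow_grid(grid, hov, 0, MedtegConfig(), rng)
        assert out.n == 5
        assert np.array_equal(out.points, grid.points)

    def test_growth_count_and_replay(self, rng):
        """Each added point must have been a Voronoi vertex of the grid
        state immediately preceding its insertion."""
        pts = np.array([[-10.0, -8.0], [12.0, -6.0], [0.0, 12.0], [2.0, -11.0]])
        pmfs = np.tile(np.full(41, 1 / 41), (4, 1))
        grid = make_grid_with_pmfs(pts, pmfs)
        hov = normative_observer(3)
        cfg = MedtegConfig()
        out = grow_grid(grid, hov, 3, cfg, np.random.default_rng(5))
        assert out.n == 7
        state = pts.copy()
        for k in range(4, 7):
            added = out.points[k]
            vor = bounded_voronoi(state, cfg.region)
            d = np.linalg.norm(vor.vertices - added, axis=1)
            assert d.min() < 1e-6
            state = np.vstack([state, added])

    def test_growth_is_seed_reproducible(self, rng):
        pts = random_grid(rng, 6)
        pmfs = np.tile(np.full(41, 1 / 41), (6, 1))
        grid = make_grid_with_pmfs(pts, pmfs)
        hov = normative_observer(1)
        cfg = MedtegConfig()
        a = grow_grid(grid, hov, 3, cfg, np.random.default_rng(42))
        b = grow_grid(grid, hov, 3, cfg, np.random.default_rng(42))
        assert np.array_equal(a.points, b.points)
        assert np.allclose(a.pmfs, b.pmfs)
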
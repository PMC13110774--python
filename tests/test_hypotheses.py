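"""Site geometry, predicted distributions and hypothesis discrimination."""

import numpy as np
import pandas as pd
import pytest

import dimerdeer as dd
from dimerdeer.errors import InvalidInputError, UndefinedScoreError
from dimerdeer.hypotheses import canonical_pair


@pytest.fixture(scope="module")
def geometry():
    return dd.SiteGeometry()


class TestPairDistribution:
    @pytest.mark.parametrize("pair, mu", [("a1-b1", 4.1), ("a1-b2", 2.5), ("a1-a2", 3.0)])
    def test_default_means(self, geometry, grid, pair, mu):
        dist = dd.pair_distribution(geometry, pair, grid)
        assert dist.mean() == pytest.approx(mu, abs=0.01)

    def test_symmetry_aliases(self):
        assert canonical_pair("b1-a2") == canonical_pair("a1-b2")
        assert canonical_pair("b1-b2") == canonical_pair("a1-a2")

    def test_narrow_sigma_concentrates_mass(self, grid):
        geom = dd.SiteGeometry({"a1-b1": (4.1, 0.001), "a1-a2": (3.0, 0.001),
                                "a1-b2": (2.5, 0.001), "a2-b2": (2.5, 0.001)})
        dist = dd.pair_distribution(geom, "a1-b2", grid)
        near = np.abs(grid.values - 2.5) <= grid.dr
        assert np.trapezoid(np.where(near, dist.density, 0), grid.values) > 0.999

    def test_unknown_pair_rejected(self, geometry, grid):
        with pytest.raises(InvalidInputError):
            dd.pair_distribution(geometry, "a1-c9", grid)


def _frames(dists, sources=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(dists)
    a = rng.normal(0, 1, (n, 3))
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1)[:, None]
    b = a + direction * np.asarray(dists)[:, None]
    return pd.DataFrame({
        "frame": np.arange(n),
        "source": sources if sources is not None else np.zeros(n, dtype=int),
        "ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2],
        "bx": b[:, 0], "by": b[:, 1], "bz": b[:, 2],
    })


class TestEmpiricalPairDistribution:
    def test_repeated_distance_gives_spike(self, grid):
        dist = dd.empirical_pair_distribution(_frames([2.0, 2.0]), grid)
        assert abs(dd.modal_distance(dist) - 2.0) <= 2 * grid.dr

    def test_large_sample_mean_converges(self, grid):
        rng = np.random.default_rng(3)
        dist = dd.empirical_pair_distribution(_frames(rng.normal(3.0, 0.1, 5000)), grid)
        assert dist.mean() == pytest.approx(3.0, abs=0.02)

    def test_zero_weight_source_is_ignored(self, grid):
        frames = _frames([2.0] * 50 + [4.0] * 50, sources=[0] * 50 + [1] * 50)
        weighted = dd.empirical_pair_distribution(
            frames, grid, weights=dd.ResidenceWeights(np.array([1.0, 0.0])))
        alone = dd.empirical_pair_distribution(_frames([2.0] * 50), grid)
        assert np.allclose(weighted.density, alone.density, atol=1e-9)

    def test_malformed_row_reported_with_position(self, grid):
        frames = _frames([2.0, 2.5, 3.0])
        frames.loc[1, "bx"] = np.nan
        with pytest.raises(InvalidInputError, match="row 1"):
            dd.empirical_pair_distribution(frames, grid)


class TestComposeHypothesis:
    def test_mixture_of_identical_parts_is_unchanged(self, geometry, grid):
        dist = dd.pair_distribution(geometry, "a1-b2", grid)
        hyp = dd.compose_hypothesis("cross", [(dist, 0.5), (dist, 0.5)])
        assert np.allclose(hyp.predicted.density, dist.density, atol=1e-12)

    def test_mixture_mean_is_weighted_mean(self, geometry, grid):
        d1 = dd.pair_distribution(geometry, "a1-b2", grid)
        d2 = dd.pair_distribution(geometry, "a1-a2", grid)
        hyp = dd.compose_hypothesis("mix", [(d1, 0.3), (d2, 0.7)])
        assert hyp.predicted.mean() == pytest.approx(
            0.3 * d1.mean() + 0.7 * d2.mean(), abs=1e-9)

    def test_symmetric_cross_pairing_is_unimodal(self, geometry, grid):
        """a1+b2 and b1+a2 superpose to one peak at 2.5 nm under symmetry."""
        d1 = dd.pair_distribution(geometry, "a1-b2", grid)
        d2 = dd.pair_distribution(geometry, "b1-a2", grid)
        hyp = dd.compose_hypothesis("cross", [(d1, 0.5), (d2, 0.5)])
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(hyp.predicted.density,
                              height=0.05 * hyp.predicted.density.max())
        assert len(peaks) == 1
        assert abs(grid.values[peaks[0]] - 2.5) <= grid.dr

    def test_empty_parts_rejected(self):
        with pytest.raises(InvalidInputError):
            dd.compose_hypothesis("x", [])


class TestScoreHypothesis:
    def test_identical_scores_one(self, geometry, grid):
        dist = dd.pair_distribution(geometry, "a1-b2", grid)
        hyp = dd.compose_hypothesis("h", [(dist, 1.0)])
        assert dd.score_hypothesis(dist, hyp) == pytest.approx(1.0, abs=1e-6)

    def test_distant_gaussians_barely_overlap(self, grid):
        near = dd.DistanceDistribution.gaussian(grid, 2.5, 0.15)
        far = dd.DistanceDistribution.gaussian(grid, 4.1, 0.15)
        hyp = dd.compose_hypothesis("far", [(far, 1.0)])
        assert dd.score_hypothesis(near, hyp) < 0.001

    def test_symmetric_in_arguments(self, grid):
        a = dd.DistanceDistribution.gaussian(grid, 2.4, 0.2)
        b = dd.DistanceDistribution.gaussian(grid, 2.8, 0.2)
        s1 = dd.score_hypothesis(a, dd.compose_hypothesis("b", [(b, 1.0)]))
        s2 = dd.score_hypothesis(b, dd.compose_hypothesis("a", [(a, 1.0)]))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_no_mass_below_limit_is_an_error(self, grid):
        dist = dd.DistanceDistribution.gaussian(grid, 4.1, 0.1)
        hyp = dd.compose_hypothesis("h", [(dist, 1.0)])
        recovered = dd.DistanceDistribution.gaussian(grid, 2.5, 0.1)
        with pytest.raises(UndefinedScoreError):
            dd.score_hypothesis(recovered, hyp, r_limit=3.0)


class TestRankHypotheses:
    def test_narrow_25_peak_selects_cross_pairing(self, geometry, grid):
        """A 2.5 nm experimental peak is consistent with the cross pairing,
        excludes both-catalytic (4.1 nm) and leaves intra-monomer (3 nm)
        below the consistency threshold."""
        recovered = dd.DistanceDistribution.gaussian(grid, 2.5, 0.12)
        ranking = dd.rank_hypotheses(recovered, dd.default_hypotheses(geometry, grid),
                                     r_limit=4.4)
        calls = {name: call for name, _, call in ranking}
        assert ranking[0][0] == "cross"
        assert calls["both-catalytic"] == "excluded"
        assert calls["intra-monomer"] != "consistent"

    def test_exact_match_ranks_first_with_unit_score(self, geometry, grid):
        hyps = dd.default_hypotheses(geometry, grid)
        recovered = hyps[1].predicted  # both-catalytic
        ranking = dd.rank_hypotheses(recovered, hyps, r_limit=6.0)
        assert ranking[0][0] == "both-catalytic"
        assert ranking[0][1] == pytest.approx(1.0, abs=1e-6)

    def test_single_hypothesis_rejected(self, geometry, grid):
        hyps = dd.default_hypotheses(geometry, grid)[:1]
        with pytest.raises(InvalidInputError):
            dd.rank_hypotheses(hyps[0].predicted, hyps)
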
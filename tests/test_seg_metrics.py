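import numpy as np
import pytest

from gradientscope import (
    NetworkPartition,
    average_bins,
    between_dispersion,
    bin_gradient,
    eccentricity,
    gradient_range,
    gradient_sd,
    network_median_distance,
    network_peak_distance,
    within_dispersion,
)
from gradientscope.core_io import GradientSet


def _gset(scores):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    return GradientSet(scores=scores,
                       explained_variance=np.full(scores.shape[1],
                                                  1.0 / scores.shape[1]))


def _part(labels):
    return NetworkPartition(
        parcel_ids=tuple(f"p{i}" for i in range(len(labels))),
        network_of=tuple(labels),
    )


class TestMedianDistance:
    def test_hand_computed_medians(self):
        g = _gset([1, 2, 3, -3, -2, -1])
        part = _part(["A"] * 3 + ["B"] * 3)
        assert network_median_distance(g, part, "A", "B") == 4.0

    def test_identical_score_multisets_give_zero(self):
        g = _gset([0.5, 1.0, 2.0, 0.5, 1.0, 2.0])
        part = _part(["A"] * 3 + ["B"] * 3)
        assert network_median_distance(g, part, "A", "B") == 0.0

    def test_matches_sort_oracle_on_random_draws(self, rng):
        scores = rng.standard_normal(1000)
        labels = ["A"] * 500 + ["B"] * 500
        g, part = _gset(scores), _part(labels)
        a, b = np.sort(scores[:500]), np.sort(scores[500:])
        med = lambda v: (v[249] + v[250]) / 2  # noqa: E731 — sorted median
        expected = abs(med(a) - med(b))
        assert network_median_distance(g, part, "A", "B") == pytest.approx(
            expected, abs=1e-12)

    def test_signed_variant(self):
        g = _gset([1, 2, 3, 4, 5, 6])
        part = _part(["A"] * 3 + ["B"] * 3)
        assert network_median_distance(g, part, "A", "B", signed=True) == -3.0

    def test_unknown_network_rejected(self):
        g = _gset([1, 2, 3, 4])
        with pytest.raises(KeyError):
            network_median_distance(g, _part(["A", "A", "B", "B"]), "A", "Z")

    def test_bounded_by_gradient_range(self, rng):
        scores = rng.standard_normal(60)
        g = _gset(scores)
        part = _part(["A"] * 30 + ["B"] * 30)
        assert network_median_distance(g, part, "A", "B") <= gradient_range(g)


class TestRangeAndSd:
    def test_constant_scores(self):
        g = _gset(np.full(10, 1.3))
        assert gradient_range(g) == 0.0
        assert gradient_sd(g) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_range(self):
        assert gradient_range(_gset([-1.0, 1.0])) == 2.0

    @pytest.mark.parametrize("c", [-2.5, 0.5, 3.0])
    def test_affine_homogeneity(self, rng, c):
        scores = rng.standard_normal(40)
        g, gc = _gset(scores), _gset(c * scores)
        assert gradient_range(gc) == pytest.approx(abs(c) * gradient_range(g))
        assert gradient_sd(gc) == pytest.approx(abs(c) * gradient_sd(g))

    def test_sample_convention(self):
        g = _gset([0.0, 1.0, 2.0])
        assert gradient_sd(g) == pytest.approx(1.0)  # ddof=1


class TestPeakDistance:
    def test_separated_tight_clusters(self, rng):
        a = -1.0 + 0.01 * rng.standard_normal(50)
        b = 1.0 + 0.01 * rng.standard_normal(50)
        g = _gset(np.concatenate([a, b]))
        part = _part(["A"] * 50 + ["B"] * 50)
        assert network_peak_distance(g, part, "A", "B") == pytest.approx(2.0,
                                                                        abs=0.05)

    def test_identical_distributions_give_zero(self, rng):
        v = rng.standard_normal(50)
        g = _gset(np.concatenate([v, v]))
        part = _part(["A"] * 50 + ["B"] * 50)
        assert network_peak_distance(g, part, "A", "B") == 0.0

    def test_dominant_mode_of_bimodal_network(self, rng):
        """Bimodal net (dominant mode 0.8) vs unimodal at −0.5 → ≈ 1.3."""
        bimodal = np.concatenate([0.8 + 0.05 * rng.standard_normal(70),
                                  -0.2 + 0.05 * rng.standard_normal(30)])
        unimodal = -0.5 + 0.05 * rng.standard_normal(60)
        g = _gset(np.concatenate([bimodal, unimodal]))
        part = _part(["A"] * 100 + ["B"] * 60)
        assert network_peak_distance(g, part, "A", "B") == pytest.approx(1.3,
                                                                        abs=0.05)

    def test_too_few_parcels_rejected(self):
        g = _gset([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        part = _part(["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError, match="5 parcels"):
            network_peak_distance(g, part, "A", "B")


class TestEccentricity:
    def test_all_at_origin(self):
        g = _gset(np.zeros((6, 3)))
        part = _part(["A"] * 3 + ["B"] * 3)
        assert eccentricity(g, part, "A") == 0.0

    def test_single_parcel_pythagoras(self):
        g = _gset(np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 0.0]]))
        part = _part(["A", "B"])
        assert eccentricity(g, part, "A") == 5.0

    def test_mean_norm_of_two_parcels(self):
        g = _gset(np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 0, 0], [0, 0, 0]]))
        part = _part(["A", "A", "B", "B"])
        assert eccentricity(g, part, "A") == 1.0

    def test_global_covers_all_parcels(self):
        g = _gset(np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 0.0]]))
        assert eccentricity(g) == 2.5

    def test_sum_sq_variant(self):
        g = _gset(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        part = _part(["A", "B"])
        assert eccentricity(g, agg="sum_sq") == 2.0

    def test_dims_exceeding_gradients_rejected(self):
        g = _gset(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="dims"):
            eccentricity(g, dims=3)


class TestDispersion:
    def test_single_parcel_within_is_zero(self):
        g = _gset(np.array([[1.0, 2.0, 3.0], [0, 0, 0], [0, 0, 0]]))
        part = _part(["A", "B", "B"])
        assert within_dispersion(g, part, "A") == 0.0

    def test_within_hand_computed(self):
        g = _gset(np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 0, 0], [0, 0, 0]]))
        part = _part(["A", "A", "B", "B"])
        assert within_dispersion(g, part, "A") == 2.0

    def test_within_translation_invariant(self, rng):
        coords = rng.standard_normal((10, 3))
        shift = np.array([2.0, -1.0, 0.5])
        part = _part(["A"] * 10 + ["B"] * 2)
        g1 = _gset(np.vstack([coords, np.zeros((2, 3))]))
        g2 = _gset(np.vstack([coords + shift, np.zeros((2, 3))]))
        assert within_dispersion(g1, part, "A") == pytest.approx(
            within_dispersion(g2, part, "A"), abs=1e-10)

    def test_between_pythagoras(self):
        g = _gset(np.array([[0.0, 0, 0], [3.0, 4.0, 0.0]]))
        part = _part(["A", "B"])
        assert between_dispersion(g, part, "A", "B") == 5.0

    def test_between_identical_sets_is_zero(self, rng):
        coords = rng.standard_normal((5, 3))
        g = _gset(np.vstack([coords, coords]))
        part = _part(["A"] * 5 + ["B"] * 5)
        assert between_dispersion(g, part, "A", "B") == 0.0

    def test_between_dims1_equals_median_distance_exactly(self, rng):
        scores = rng.standard_normal((40, 3))
        g = _gset(scores)
        part = _part(["A"] * 15 + ["B"] * 25)
        assert between_dispersion(g, part, "A", "B", dims=1) == \
            network_median_distance(g, part, "A", "B")


class TestRelabelingInvariance:
    def test_metrics_invariant_within_networks(self, rng):
        scores = rng.standard_normal((30, 3))
        labels = ["A"] * 10 + ["B"] * 20
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(20)])
        g1, g2 = _gset(scores), _gset(scores[perm])
        p = _part(labels)
        for metric in (
            lambda g: network_median_distance(g, p, "A", "B"),
            lambda g: eccentricity(g, p, "A"),
            lambda g: within_dispersion(g, p, "B"),
            lambda g: between_dispersion(g, p, "A", "B"),
            gradient_range,
            gradient_sd,
        ):
            assert metric(g1) == pytest.approx(metric(g2), abs=1e-12)


class TestBinning:
    def test_uniform_scores_fill_bins_evenly(self):
        scores = np.linspace(0, 1, 500, endpoint=False) + 1e-4
        dist = bin_gradient(_gset(scores), edges=np.linspace(0, 1, 51))
        np.testing.assert_array_equal(dist.counts, 10.0)

    def test_counts_conserve_parcels(self, rng):
        g = _gset(rng.standard_normal(400))
        dist = bin_gradient(g, n_bins=50)
        assert dist.counts.sum() == 400
        assert dist.edges.size == 51

    def test_average_of_identical_is_identity(self, rng):
        g = _gset(rng.standard_normal(100))
        d = bin_gradient(g, n_bins=50)
        avg = average_bins([d, d, d])
        np.testing.assert_array_equal(avg.counts, d.counts)

    def test_average_conserves_total(self, rng):
        edges = np.linspace(-4, 4, 51)
        dists = [bin_gradient(_gset(rng.uniform(-3.9, 3.9, 400)), edges=edges)
                 for _ in range(5)]
        avg = average_bins(dists)
        assert avg.counts.sum() == pytest.approx(400.0)

    def test_edge_mismatch_rejected(self, rng):
        d1 = bin_gradient(_gset(rng.standard_normal(50)),
                          edges=np.linspace(-3, 3, 51))
        d2 = bin_gradient(_gset(rng.standard_normal(50)),
                          edges=np.linspace(-4, 4, 51))
        with pytest.raises(ValueError, match="edges"):
            average_bins([d1, d2])

    def test_network_stratified_counts_sum_to_sizes(self, rng):
        g = _gset(rng.standard_normal(20))
        part = _part(["A"] * 8 + ["B"] * 12)
        dist = bin_gradient(g, n_bins=10, part=part)
        assert dist.per_network["A"].sum() == 8
        assert dist.per_network["B"].sum() == 12
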
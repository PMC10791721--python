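import numpy as np
import pytest
from scipy.stats import spearmanr

from gradientscope import (
    CohortSpec,
    apply_exclusions,
    compute_fd,
    gsq_item_table,
    score_aq,
    score_gsq,
    simulate_cohort,
    simulate_connectome,
    simulate_motion,
    simulate_traits,
)
from gradientscope.pipeline import median_distance_series
from gradientscope.synthetic import NETWORK_NAMES, make_partition


class TestSampleAccounting:
    def test_study_exclusion_arithmetic(self):
        assert apply_exclusions(401, (23, 5, 3)) == 370

    def test_over_exclusion_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            apply_exclusions(10, (11,))


class TestSpecValidation:
    def test_partition_sizes_default_to_atlas_proportions(self):
        spec = CohortSpec(n_subjects=2, n_parcels=400)
        assert spec.partition_sizes == (61, 77, 46, 47, 52, 26, 91)

    def test_sizes_sum_to_parcels_at_any_scale(self):
        for p in (40, 100, 173, 400):
            spec = CohortSpec(n_subjects=2, n_parcels=p)
            assert sum(spec.partition_sizes) == p
            assert min(spec.partition_sizes) >= 1

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CohortSpec(n_subjects=2, n_parcels=10,
                       partition_sizes=(1, 1, 1, 1, 1, 1, 5))

    def test_bad_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(planted_spearman=1.5)


class TestTraits:
    def test_moments_match_targets_at_large_n(self):
        spec = CohortSpec(n_subjects=4000, n_parcels=14)
        table, _, _, _ = simulate_traits(spec, seed=11)
        assert table["gsq_total"].mean() == pytest.approx(50.1, rel=0.02)
        assert table["gsq_total"].std() == pytest.approx(18.2, rel=0.05)
        assert table["aq_total"].mean() == pytest.approx(19.6, rel=0.02)
        assert table["aq_total"].std() == pytest.approx(5.3, rel=0.05)

    def test_same_seed_reproduces_table(self):
        spec = CohortSpec(n_subjects=25, n_parcels=14)
        t1, a1, g1, k1 = simulate_traits(spec, seed=5)
        t2, a2, g2, k2 = simulate_traits(spec, seed=5)
        assert t1.equals(t2) and a1.equals(a2) and g1.equals(g2) and k1 == k2

    def test_item_responses_reproduce_totals(self):
        spec = CohortSpec(n_subjects=20, n_parcels=14)
        table, aq_items, gsq_items, key = simulate_traits(spec, seed=3)
        items = gsq_item_table()
        for _, row in table.iterrows():
            aq_resp = aq_items.set_index("subject_id").loc[row["subject_id"]]
            gsq_resp = gsq_items.set_index("subject_id").loc[row["subject_id"]]
            assert score_aq(aq_resp.to_numpy(), key) == row["aq_total"]
            assert score_gsq(gsq_resp.to_numpy(), items) == row["gsq_total"]

    def test_subscale_structure_holds(self):
        spec = CohortSpec(n_subjects=30, n_parcels=14)
        table, _, _, _ = simulate_traits(spec, seed=8)
        assert (table["gsq_hyper"] + table["gsq_hypo"] ==
                table["gsq_total"]).all()
        modality_sum = sum(table[f"gsq_{m}"] for m in
                           ("vision", "hearing", "olfaction", "taste", "touch",
                            "proprioception", "vestibular"))
        assert (modality_sum == table["gsq_total"]).all()
        assert (table["gsq_total"] - table["gsq_vision"] ==
                table["gsq_no_vision"]).all()

    def test_totals_within_scale_ranges(self):
        spec = CohortSpec(n_subjects=200, n_parcels=14)
        table, _, _, _ = simulate_traits(spec, seed=2)
        assert table["aq_total"].between(0, 50).all()
        assert table["gsq_total"].between(0, 168).all()


class TestConnectome:
    def test_matrix_is_valid_connectivity(self):
        spec = CohortSpec(n_subjects=2, n_parcels=60)
        m = simulate_connectome(1.0, spec, np.random.default_rng(0))
        assert m.n_parcels == 60
        assert np.allclose(m.values, m.values.T)
        assert np.abs(m.values[~np.eye(60, dtype=bool)]).max() <= 0.99

    def test_degenerate_limit_shares_one_matrix(self):
        """β_expand = 0 and vanishing noise: all subjects nearly identical."""
        spec = CohortSpec(n_subjects=3, n_parcels=40, beta_expand=0.0,
                          sigma_parcel=1e-9, sigma_edge=1e-9)
        c = simulate_cohort(spec, seed=1, include_motion=False)
        np.testing.assert_allclose(c.matrices[0].values, c.matrices[1].values,
                                   atol=1e-6)

    def test_distance_increases_with_expansion_without_noise(self):
        """Measured Vis–Default separation rises with the expansion factor
        when generator noise is (numerically) switched off. Strict pointwise
        monotonicity is not attainable — the 95% row threshold makes survivor
        sets change discretely with the geometry — so the check is on the
        rank ordering of the transfer."""
        spec = CohortSpec(n_subjects=10, n_parcels=100, sigma_parcel=1e-9,
                          sigma_edge=1e-9)
        part = make_partition(spec)
        expansions = np.linspace(0.6, 1.1, 10)
        mats = [simulate_connectome(e, spec, np.random.default_rng(i),
                                    parcel_ids=part.parcel_ids)
                for i, e in enumerate(expansions)]
        d = median_distance_series(mats, part)
        assert spearmanr(expansions, d).statistic >= 0.9
        assert d[-1] > d[0]

    def test_nonpositive_expansion_rejected(self):
        spec = CohortSpec(n_subjects=2, n_parcels=40)
        with pytest.raises(ValueError, match="positive"):
            simulate_connectome(0.0, spec, np.random.default_rng(0))


class TestMotion:
    def test_zero_target_fd_gives_zero(self):
        spec = CohortSpec(n_subjects=2, n_parcels=14, target_fd=0.0,
                          n_timepoints=30, n_voxels=10)
        traces, _ = simulate_motion(spec, np.random.default_rng(0))
        assert compute_fd(traces) == 0.0

    def test_fd_calibration_hits_target(self):
        spec = CohortSpec(n_subjects=2, n_parcels=14, target_fd=0.03,
                          n_timepoints=200, n_voxels=10)
        fds = [compute_fd(simulate_motion(spec, np.random.default_rng(k))[0])
               for k in range(200)]
        assert np.mean(fds) == pytest.approx(0.03, rel=0.1)

    def test_different_seeds_differ(self):
        spec = CohortSpec(n_subjects=2, n_parcels=14, n_timepoints=30,
                          n_voxels=10)
        t1, _ = simulate_motion(spec, np.random.default_rng(1))
        t2, _ = simulate_motion(spec, np.random.default_rng(2))
        assert np.abs(t1 - t2).max() > 0


class TestCohort:
    def test_partition_names_and_order(self):
        spec = CohortSpec(n_subjects=2, n_parcels=100)
        part = make_partition(spec)
        assert part.network_order == NETWORK_NAMES
        assert part.n_parcels == 100

    def test_cohort_determinism(self):
        spec = CohortSpec(n_subjects=5, n_parcels=40, n_timepoints=20,
                          n_voxels=10)
        c1 = simulate_cohort(spec, seed=9)
        c2 = simulate_cohort(spec, seed=9)
        assert c1.participants.equals(c2.participants)
        np.testing.assert_array_equal(c1.matrices[3].values,
                                      c2.matrices[3].values)

    def test_planted_effect_visible_in_cohort(self, planted_cohort):
        c = planted_cohort
        d = median_distance_series(c.matrices, c.partition)
        rho = spearmanr(c.participants["gsq_total"], d).statistic
        assert rho > 0.3  # strong planted coupling (0.7) at n=60

    def test_null_grid_family_wise_error_under_bonferroni(self):
        """β_expand = 0 cohorts: ≤ ~5% of replicates flag any of the 42
        median-distance tests at the Bonferroni threshold."""
        from gradientscope import bonferroni_threshold, spearman
        from gradientscope.seg_metrics import network_median_distance
        from gradientscope.connectome import group_average
        from gradientscope.gradients import GradientEmbedding

        reps, hits = 40, 0
        for k in range(reps):
            spec = CohortSpec(n_subjects=30, n_parcels=60, beta_expand=0.0,
                              planted_spearman=0.0)
            c = simulate_cohort(spec, seed=2000 + k, include_motion=False)
            emb = GradientEmbedding().fit(group_average(c.matrices).values)
            gsets = [emb.transform_set(m.values) for m in c.matrices]
            thr = bonferroni_threshold(0.05, 42)
            pmin = 1.0
            for na, nb in c.partition.pairs():
                d = np.array([network_median_distance(g, c.partition, na, nb)
                              for g in gsets])
                for trait in ("aq_total", "gsq_total"):
                    t = c.participants[trait].to_numpy(float)
                    _, p = spearman(d, t)
                    pmin = min(pmin, p)
            hits += pmin < thr
        assert hits / reps <= 0.07 + 0.05  # small-rep slack on binomial noise
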
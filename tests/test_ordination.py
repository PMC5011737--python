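"""PCoA and CAP against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa
from statsmodels.multivariate.cancorr import CanCorr

from stygovector import CAP, CommunitySpec, PCoA, simulate_community
from stygovector.ordination import _distinct_label_orders


class TestPCoA:
    def test_two_points_single_axis_closed_form(self):
        d = 0.8
        pc = PCoA().fit(np.array([[0, d], [d, 0]]))
        assert pc.positive_eigenvalues_ == pytest.approx([d**2 / 2])
        assert pc.axes_.shape == (2, 1)

    def test_euclidean_round_trip(self, euclidean_config):
        _, D = euclidean_config
        pc = PCoA().fit(D)
        rec = cdist(pc.coordinates_, pc.coordinates_)
        assert np.abs(rec - D).max() < 1e-10
        assert pc.negative_eigenvalue_mass_ == pytest.approx(0.0, abs=1e-12)

    def test_identical_points_have_no_positive_axes(self):
        pc = PCoA().fit(np.zeros((4, 4)))
        assert pc.axes_.shape[1] == 0
        assert np.allclose(pc.eigenvalues_, 0.0, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            PCoA().fit(D)

    def test_matches_scikit_bio_reference(self, three_group_community):
        from stygovector import bray_curtis, sqrt_transform

        counts, _ = three_group_community
        dm = bray_curtis(sqrt_transform(counts))
        mine = PCoA().fit(dm)
        ref = skbio_pcoa(DistanceMatrix(dm.data), number_of_dimensions=0)
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        k = mine.positive_eigenvalues_.size
        assert mine.positive_eigenvalues_ == pytest.approx(ref_eig[:k], abs=1e-9)
        # scaled coordinates agree up to per-axis sign
        ref_coords = ref.samples.to_numpy()[:, :k]
        for j in range(k):
            col, refcol = mine.coordinates_[:, j], ref_coords[:, j]
            assert min(np.abs(col - refcol).max(), np.abs(col + refcol).max()) < 1e-8

    def test_add_a_point_projection_recovers_held_out_point(self, euclidean_config):
        pts, _ = euclidean_config
        train, new = pts[:-1], pts[-1:]
        D_train = cdist(train, train)
        pc = PCoA().fit(D_train)
        q = pc.project(cdist(new, train))
        # projected scaled coordinates must reproduce distances to training pts
        new_coords = q * np.sqrt(pc.positive_eigenvalues_)
        rec = np.linalg.norm(pc.coordinates_ - new_coords, axis=1)
        assert np.abs(rec - cdist(new, train).ravel()).max() < 1e-10

    def test_training_rows_project_onto_themselves(self, euclidean_config):
        _, D = euclidean_config
        pc = PCoA().fit(D)
        assert np.abs(pc.project(D) - pc.axes_).max() < 1e-9


class TestCAPStatistics:
    def test_perfect_separation_gives_unit_correlation(self):
        D = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
        )
        m = CAP(m=1, n_permutations=0, metric="precomputed").fit(D, ["a", "a", "b", "b"])
        assert m.delta_sq_ == pytest.approx([1.0])
        assert m.trace_ == pytest.approx(1.0)

    def test_delta_sq_matches_statsmodels_cancorr(self, three_group_community):
        counts, meta = three_group_community
        m = CAP(m=6, n_permutations=0).fit(counts, meta["group"])
        Q = m.pcoa_.axes_[:, :6]
        y = meta["group"].to_numpy()
        dummies = (y[:, None] == np.unique(y)[None, :]).astype(float)[:, :-1]
        ref = CanCorr(dummies - dummies.mean(0), Q - Q.mean(0))
        assert m.delta_sq_ == pytest.approx(ref.cancorr**2, abs=1e-10)

    def test_invariance_under_relabeling_and_sample_order(self, three_group_community):
        counts, meta = three_group_community
        y = meta["group"].to_numpy()
        base = CAP(m=5, n_permutations=0).fit(counts, y)
        relabel = CAP(m=5, n_permutations=0).fit(
            counts, np.char.add("grp_", y.astype(str))
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        shuffled = CAP(m=5, n_permutations=0).fit(counts.iloc[perm], y[perm])
        for other in (relabel, shuffled):
            assert other.delta_sq_ == pytest.approx(base.delta_sq_, abs=1e-9)
            assert other.trace_ == pytest.approx(base.trace_, abs=1e-9)

    def test_m_above_rank_reduced_with_warning(self, three_group_community):
        counts, meta = three_group_community
        with pytest.warns(UserWarning, match="positive PCoA rank"):
            m = CAP(m=99, n_permutations=0).fit(counts, meta["group"])
        assert m.m_ <= counts.shape[0] - 1


class TestPermutationTest:
    def test_exact_p_equals_brute_force_enumeration(self):
        # n=6, two groups of 3: 20 distinct relabelings; oracle recomputes the
        # squared canonical correlation per labeling by linear regression
        # (valid because the PCo axes are orthonormal), a different route than
        # the SVD the estimator uses.
        counts, meta = simulate_community(
            CommunitySpec(groups=(("a", 3), ("b", 3)), n_taxa=15,
                          depth_mean=500, effect_size=1.0, seed=9)
        )
        fit = CAP(m=3, permutation="exact").fit(counts, meta["group"])
        assert fit.n_permutations_ == 20
        Q = fit.pcoa_.axes_[:, :3]

        def r_squared(labels):
            x = (np.asarray(labels) == np.asarray(labels)[0]).astype(float)
            x = x - x.mean()
            beta, *_ = np.linalg.lstsq(Q, x, rcond=None)
            resid = x - Q @ beta
            return 1.0 - (resid**2).sum() / (x**2).sum()

        obs = r_squared(meta["group"])
        stats = np.array(
            [r_squared(p) for p in _distinct_label_orders(meta["group"].to_numpy())]
        )
        p_oracle = np.mean(stats >= obs - 1e-12)
        assert fit.p_delta_sq_ == pytest.approx(p_oracle)
        assert fit.p_trace_ == pytest.approx(p_oracle)  # g=2: trace == delta1^2

    def test_random_permutation_p_has_plus_one_correction(self):
        D = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
        )
        m = CAP(m=1, n_permutations=99, metric="precomputed",
                random_state=0).fit(D, ["a", "a", "b", "b"])
        assert 1 / 100 <= m.p_trace_ <= 1.0

    def test_null_labels_rarely_significant_over_seeded_runs(self):
        # one homogeneous cloud, random labels: p > 0.05 in >= 94 of 100 runs
        ok = 0
        for s in range(100):
            counts, meta = simulate_community(
                CommunitySpec(effect_size=0.0, seed=2_000 + s, n_taxa=40,
                              groups=(("a", 5), ("b", 5), ("c", 5)),
                              depth_mean=2000)
            )
            m = CAP(m=8, n_permutations=199, random_state=s).fit(
                counts, meta["group"]
            )
            ok += m.p_trace_ > 0.05
        assert ok >= 94


class TestAllocation:
    def test_loo_reaches_100_percent_on_separated_groups(self):
        counts, meta = simulate_community(CommunitySpec(effect_size=5.0, seed=1))
        m = CAP(m=11, n_permutations=0).fit(counts, meta["group"])
        alloc = m.loo_allocation()
        assert alloc.loc["total", "success_pct"] == 100.0
        assert (alloc["success_pct"] == 100.0).all()

    def test_single_misplaced_sample_scores_n_minus_one_over_n(self):
        # two tight clusters; one "a" sample sits exactly in the "b" cluster
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=(5, 2))
        b = rng.normal(5.0, 0.01, size=(5, 2)) + np.array([0.0, 5.0])
        pts = np.vstack([a[:4], b[0] + 1e-3, b])  # 5th 'a' point inside b
        y = ["a"] * 5 + ["b"] * 5
        D = cdist(pts, pts)
        m = CAP(m=2, n_permutations=0, metric="precomputed").fit(D, y)
        alloc = m.loo_allocation()
        assert alloc.loc["total", "correct"] == 9
        assert alloc.loc["total", "success_pct"] == pytest.approx(90.0)

    def test_chance_level_allocation_for_shuffled_labels(self):
        totals = []
        for s in range(40):
            counts, meta = simulate_community(
                CommunitySpec(effect_size=0.0, seed=4_000 + s, n_taxa=40,
                              groups=(("a", 5), ("b", 5), ("c", 5)),
                              depth_mean=2000)
            )
            m = CAP(m=8, n_permutations=0).fit(counts, meta["group"])
            totals.append(m.loo_allocation().loc["total", "success_pct"])
        # 3 groups -> chance is ~33%; allow generous Monte-Carlo slack
        assert abs(np.mean(totals) - 100.0 / 3.0) < 10.0

    def test_singleton_group_is_structural_miss(self):
        counts, meta = simulate_community(
            CommunitySpec(effect_size=5.0, seed=3,
                          groups=(("a", 4), ("b", 4), ("solo", 1)))
        )
        m = CAP(m=4, n_permutations=0).fit(counts, meta["group"])
        with pytest.warns(UserWarning, match="structural"):
            alloc = m.loo_allocation()
        assert alloc.loc["solo", "correct"] == 0

    def test_predict_recovers_training_groups_when_separated(self):
        counts, meta = simulate_community(CommunitySpec(effect_size=5.0, seed=6))
        m = CAP(m=8, n_permutations=0).fit(counts, meta["group"])
        assert (m.predict(counts) == meta["group"].to_numpy()).all()
        assert m.score(counts, meta["group"]) == 1.0
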
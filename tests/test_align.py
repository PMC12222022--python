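import numpy as np
import pytest

from nociscope.align import (
    AlignmentError,
    GuidePostSet,
    SimilarityParams,
    chain_rounds,
    fit_similarity,
    fit_warp,
    transfer_labels,
)
from nociscope.simulate import simulate_fields

from _oracles import similarity_closed_form


def apply_sim(scale, rot_deg, t, pts):
    return SimilarityParams(scale, rot_deg, (t[0], t[1])).apply(pts)


class TestFitSimilarity:
    def test_identity_recovered_to_machine_precision(self, rng):
        pts = rng.uniform(0, 500, (30, 2))
        fit = fit_similarity(GuidePostSet(ish=pts, invivo=pts.copy()))
        assert fit.scale == pytest.approx(1.0, abs=1e-12)
        assert fit.rotation_deg == pytest.approx(0.0, abs=1e-10)
        assert fit.translation == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_exact_recovery_of_synthetic_transform(self, rng):
        src = rng.uniform(0, 500, (100, 2))
        dst = apply_sim(1.2, 10.0, (5.0, -3.0), src)
        fit = fit_similarity(GuidePostSet(ish=src, invivo=dst))
        assert fit.scale == pytest.approx(1.2, abs=1e-12)
        assert fit.rotation_deg == pytest.approx(10.0, abs=1e-10)
        assert fit.translation == pytest.approx((5.0, -3.0), abs=1e-8)

    def test_agrees_with_closed_form_oracle_under_jitter(self, rng):
        """With noisy correspondences both routes solve the same least-squares
        problem; the library fit must match the hand-written Procrustes
        solution."""
        src = rng.uniform(0, 500, (50, 2))
        dst = apply_sim(0.9, -25.0, (40.0, 12.0), src) + rng.normal(0, 3, (50, 2))
        fit = fit_similarity(GuidePostSet(ish=src, invivo=dst))
        scale, rot, t = similarity_closed_form(src, dst)
        assert fit.scale == pytest.approx(scale, rel=1e-9)
        assert fit.rotation_deg == pytest.approx(rot, abs=1e-9)
        assert fit.translation == pytest.approx(t, abs=1e-6)

    def test_residual_rms_matches_chi_expectation(self, rng):
        """At jitter sd=1 px the residual sum of squares has expectation
        sigma^2 (2n - 4) (four similarity parameters); the mean over
        replicates must sit in its 99% CI."""
        n, sd, reps = 100, 1.0, 60
        rss = []
        for _ in range(reps):
            src = rng.uniform(0, 500, (n, 2))
            dst = apply_sim(1.1, 15.0, (3.0, 4.0), src) + rng.normal(0, sd, (n, 2))
            fit = fit_similarity(GuidePostSet(ish=src, invivo=dst))
            res = SimilarityParams(fit.scale, fit.rotation_deg, fit.translation).apply(src) - dst
            rss.append((res**2).sum())
        dof = 2 * n - 4
        mu = sd**2 * dof
        half = 2.576 * sd**2 * np.sqrt(2 * dof) / np.sqrt(reps)
        assert abs(np.mean(rss) - mu) < half

    def test_relabeling_invariance(self, rng):
        src = rng.uniform(0, 500, (40, 2))
        dst = apply_sim(1.3, 33.0, (-7.0, 2.0), src) + rng.normal(0, 1, (40, 2))
        perm = rng.permutation(40)
        a = fit_similarity(GuidePostSet(ish=src, invivo=dst))
        b = fit_similarity(GuidePostSet(ish=src[perm], invivo=dst[perm]))
        assert a.scale == pytest.approx(b.scale, rel=1e-12)
        assert a.rotation_deg == pytest.approx(b.rotation_deg, abs=1e-10)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(AlignmentError, match="collinear"):
            fit_similarity(GuidePostSet(ish=pts, invivo=pts))

    def test_fewer_than_three_pairs_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(AlignmentError, match="3"):
            fit_similarity(GuidePostSet(ish=pts, invivo=pts))

    def test_duplicate_ish_points_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(AlignmentError, match="duplicate"):
            GuidePostSet(ish=pts, invivo=pts)


class TestFitWarp:
    def test_tps_interpolates_guideposts_exactly(self, rng):
        src = rng.uniform(0, 400, (25, 2))
        dst = src + rng.normal(0, 10, (25, 2))
        model = fit_warp(GuidePostSet(ish=src, invivo=dst), "thin_plate_spline")
        assert np.max(model.residuals) < 1e-8

    def test_recovers_smooth_sinusoidal_field(self):
        """40 guide-posts on a known low-frequency deformation: the fitted
        warp maps held-out points within a small fraction of the deformation
        amplitude."""
        fs = simulate_fields(
            n_points=200, scale=1.1, rotation_deg=8.0, warp_amplitude=8.0,
            jitter_sd=0.0, guidepost_fraction=0.2, seed=3,
        )
        model = fit_warp(fs.guideposts(), "thin_plate_spline")
        held_out = np.setdiff1d(np.arange(200), fs.guidepost_idx)
        mapped = model.transform(fs.ish[held_out])
        err = np.linalg.norm(mapped - fs.invivo[held_out], axis=1)
        assert np.median(err) < 2.0  # px, vs 8 px deformation amplitude

    def test_three_landmark_piecewise_affine_is_exact_affine(self):
        src = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        A = np.array([[1.1, 0.2], [-0.1, 0.95]])
        b = np.array([5.0, -2.0])
        dst = src @ A.T + b
        model = fit_warp(GuidePostSet(ish=src, invivo=dst), "piecewise_affine")
        probe = np.array([[20.0, 30.0], [50.0, 10.0]])
        np.testing.assert_allclose(model.transform(probe), probe @ A.T + b, atol=1e-8)

    def test_unknown_method_rejected(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        with pytest.raises(AlignmentError, match="unknown warp"):
            fit_warp(GuidePostSet(ish=pts, invivo=pts), "rubber_sheet")


class TestTransferLabels:
    def test_identical_point_sets_match_perfectly(self, rng):
        pts = rng.uniform(0, 500, (80, 2))
        res = transfer_labels(pts, pts.copy(), None, max_dist=1.0)
        assert res.n_matched == 80
        assert all(i == j for i, j in res.pairs)

    def test_displaced_cell_left_unmatched(self, rng):
        pts = rng.uniform(0, 500, (20, 2))
        rois = pts.copy()
        rois[7] += 500.0  # push one cell far beyond max_dist
        res = transfer_labels(pts, rois, None, max_dist=5.0)
        assert res.n_matched == 19
        assert res.n_beyond_max_dist == 1

    def test_default_synthetic_field_accuracy(self):
        """Default deformation with correspondence jitter at 20% of
        nearest-neighbour spacing: at least 99% of the assignments made are
        correct (cells displaced beyond max_dist are dropped, per the
        one-to-one matching contract), and most cells are matched."""
        total_correct = total_matched = total_cells = 0
        for seed in range(6):
            fs = simulate_fields(
                n_points=150, scale=1.1, rotation_deg=8.0, warp_amplitude=6.0,
                jitter_sd=0.0, guidepost_fraction=0.3, seed=seed,
            )
            rng = np.random.default_rng(seed + 500)
            invivo = fs.invivo + rng.normal(0, 0.2 * fs.nn_spacing, fs.invivo.shape)
            model = fit_warp(
                GuidePostSet(ish=fs.ish[fs.guidepost_idx], invivo=invivo[fs.guidepost_idx])
            )
            res = transfer_labels(fs.ish, invivo, model, max_dist=0.5 * fs.nn_spacing)
            total_correct += sum(1 for i, j in res.pairs if i == j)
            total_matched += res.n_matched
            total_cells += len(fs.ish)
        assert total_correct / total_matched >= 0.99
        assert total_matched / total_cells >= 0.75

    def test_empty_roi_set(self):
        res = transfer_labels(np.zeros((3, 2)), np.empty((0, 2)), None, 5.0)
        assert res.pairs == ()


class TestChainRounds:
    @staticmethod
    def sim_model(scale, rot, t):
        from nociscope.align import RegistrationModel

        return RegistrationModel(similarity=SimilarityParams(scale, rot, t))

    def test_chain_of_identities_is_identity(self, rng):
        ident = self.sim_model(1.0, 0.0, (0.0, 0.0))
        comp, _ = chain_rounds([ident, ident, ident])
        pts = rng.uniform(0, 100, (10, 2))
        np.testing.assert_allclose(comp.transform(pts), pts, atol=1e-12)

    def test_two_similarities_compose_to_matrix_product(self, rng):
        m1 = self.sim_model(1.2, 10.0, (5.0, -3.0))
        m2 = self.sim_model(0.9, -25.0, (1.0, 8.0))
        comp, _ = chain_rounds([m1, m2])
        pts = rng.uniform(0, 100, (20, 2))
        M = m2.similarity.matrix() @ m1.similarity.matrix()
        expected = (M @ np.column_stack([pts, np.ones(20)]).T).T[:, :2]
        np.testing.assert_allclose(comp.transform(pts), expected, atol=1e-9)

    def test_three_rounds_error_bounded_by_sum_of_per_round_errors(self, rng):
        """Triangle inequality on ground truth: chaining three noisy rounds
        cannot exceed the sum of single-round mapping errors (checked on a
        shared probe set)."""
        pts = rng.uniform(0, 300, (40, 2))
        stages = [pts]
        models = []
        for k in range(3):
            src = stages[-1]
            dst = apply_sim(1.05, 5.0, (2.0, 1.0), src) + rng.normal(0, 0.5, src.shape)
            gp = GuidePostSet(ish=src, invivo=dst)
            models.append(fit_warp(gp, "thin_plate_spline"))
            stages.append(dst)
        comp, _ = chain_rounds(models)
        probe = pts
        end_err = np.linalg.norm(comp.transform(probe) - stages[-1], axis=1)
        per_round = sum(
            np.linalg.norm(m.transform(s) - s_next, axis=1)
            for m, s, s_next in zip(models, stages, stages[1:])
        )
        assert np.all(end_err <= per_round.sum() + 1e-6)

    def test_empty_chain_rejected(self):
        with pytest.raises(AlignmentError):
            chain_rounds([])
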
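import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_tensors
from tbikit.dti import (compute_metrics, eigensystem, fa_from_eigenvalues,
                        fit_tensor_loglinear, fit_tensor_nonlinear,
                        metric_maps, tensor_to_components)
from tbikit.phantom import PhantomSpec, build_tensor_phantom, synthesize_dwi
from tbikit.scheme import make_scheme


class TestFitting:
    def test_loglinear_recovers_noise_free_tensors(self, scheme, rng):
        D, _ = random_tensors(rng, 50)
        comps = tensor_to_components(D)
        S = synthesize_dwi(comps, scheme, s0=500.0, snr=np.inf)
        est, s0 = fit_tensor_loglinear(S, scheme)
        assert np.abs(est - comps).max() / np.abs(comps).max() < 1e-10
        assert np.allclose(s0, 500.0)

    def test_constant_signal_gives_zero_tensor(self, scheme):
        S = np.full((1, scheme.n_volumes), 123.0)
        est, s0 = fit_tensor_loglinear(S, scheme)
        assert np.abs(est).max() < 1e-12
        assert s0[0] == pytest.approx(123.0)

    def test_loglinear_fa_matches_closed_form(self, scheme):
        ev = np.array([1.5e-3, 0.4e-3, 0.3e-3])
        comps = tensor_to_components(np.diag(ev))
        S = synthesize_dwi(comps[None], scheme, s0=100.0, snr=np.inf)
        est, _ = fit_tensor_loglinear(S, scheme)
        w, _, _ = eigensystem(est)
        assert fa_from_eigenvalues(w)[0] == pytest.approx(
            float(fa_from_eigenvalues(ev)), abs=1e-10)

    def test_nonlinear_noise_free_round_trip(self, scheme, rng):
        D, _ = random_tensors(rng, 50)
        comps = tensor_to_components(D)
        S = synthesize_dwi(comps, scheme, s0=800.0, snr=np.inf)
        c0, z0 = fit_tensor_loglinear(S, scheme)
        est, s0, conv = fit_tensor_nonlinear(S, scheme, c0, z0)
        assert conv.all()
        assert np.abs(est - comps).max() / np.abs(comps).max() < 1e-8

    def test_nonlinear_from_optimal_init_is_stable(self, scheme):
        comps = tensor_to_components(np.diag([1.0e-3, 0.3e-3, 0.2e-3]))[None]
        S = synthesize_dwi(comps, scheme, s0=100.0, snr=np.inf)
        est, s0, conv = fit_tensor_nonlinear(S, scheme, comps, np.array([100.0]),
                                             max_iter=1)
        assert conv.all()
        assert np.allclose(est, comps, rtol=0, atol=1e-15)

    def test_rank_deficient_scheme_raises(self):
        from tbikit.scheme import AcquisitionScheme
        from tbikit.dti import SingularFitError
        g = np.tile([1.0, 0.0, 0.0], (8, 1))
        sch = AcquisitionScheme(np.r_[0.0, np.full(7, 1000.0)],
                                np.vstack([[0, 0, 1.0], g[:7]]), n_b0=1)
        with pytest.raises(SingularFitError):
            fit_tensor_loglinear(np.ones((1, 8)), sch)

    def test_fa_bias_decreases_with_snr(self, scheme):
        ev = np.array([1.0e-3, 0.25e-3, 0.25e-3])  # FA = 1/sqrt(2)
        comps = np.tile(tensor_to_components(np.diag(ev)), (300, 1))
        fa_true = float(fa_from_eigenvalues(ev))
        biases = []
        for snr in (20.0, 40.0, 80.0):
            S = synthesize_dwi(comps, scheme, s0=1000.0, snr=snr, seed=9)
            c0, z0 = fit_tensor_loglinear(S, scheme)
            c, z, _ = fit_tensor_nonlinear(S, scheme, c0, z0)
            w, _, _ = eigensystem(c)
            biases.append(abs(np.median(fa_from_eigenvalues(w)) - fa_true))
        assert biases[0] >= biases[1] >= biases[2] or np.max(biases) < 5e-3


class TestEigensystem:
    def test_diagonal_tensor(self):
        w, v, clamped = eigensystem(np.diag([3e-4, 2e-4, 1e-4]))
        np.testing.assert_allclose(w, [3e-4, 2e-4, 1e-4])
        assert not clamped

    def test_similarity_invariance(self, rng):
        ev = np.array([3e-4, 2e-4, 1e-4])
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        w, v, _ = eigensystem(Q @ np.diag(ev) @ Q.T)
        np.testing.assert_allclose(w, ev, rtol=1e-10)
        # eigenvector matrix orthonormal
        np.testing.assert_allclose(v @ v.T, np.eye(3), atol=1e-8)

    def test_negative_eigenvalue_clamped_and_flagged(self):
        w, _, clamped = eigensystem(np.diag([3e-4, 2e-4, -1e-5]), clamp=True)
        assert w[2] == pytest.approx(1e-12)
        assert clamped
        w2, _, flag2 = eigensystem(np.diag([3e-4, 2e-4, -1e-5]), clamp=False)
        assert w2[2] == pytest.approx(-1e-5)
        assert flag2


class TestMetrics:
    @pytest.mark.parametrize("convention", ["trace", "lambda1"])
    def test_isotropic(self, convention):
        m = compute_metrics(np.array([1e-3, 1e-3, 1e-3]), convention)
        assert m["FA"] == pytest.approx(0.0, abs=1e-15)
        assert m["T"] == pytest.approx(3e-3)
        assert m["AD"] == pytest.approx(1e-3)
        assert m["RD"] == pytest.approx(1e-3)
        assert m["WL"] == pytest.approx(0.0) and m["WP"] == pytest.approx(0.0)

    @pytest.mark.parametrize("convention", ["trace", "lambda1"])
    def test_pure_prolate(self, convention):
        m = compute_metrics(np.array([1.0, 0.0, 0.0]), convention)
        assert m["FA"] == pytest.approx(1.0)
        assert m["WL"] == pytest.approx(1.0) and m["WP"] == pytest.approx(0.0)

    @pytest.mark.parametrize("convention", ["trace", "lambda1"])
    def test_pure_oblate(self, convention):
        m = compute_metrics(np.array([1.0, 1.0, 0.0]), convention)
        assert m["FA"] == pytest.approx(1 / np.sqrt(2))
        assert m["WL"] == pytest.approx(0.0) and m["WP"] == pytest.approx(1.0)

    def test_210_distinguishes_conventions(self):
        l = np.array([2.0, 1.0, 0.0])
        mt = compute_metrics(l, "trace")
        assert mt["WL"] == pytest.approx(1 / 3) and mt["WP"] == pytest.approx(2 / 3)
        ml = compute_metrics(l, "lambda1")
        assert ml["WL"] == pytest.approx(0.5) and ml["WP"] == pytest.approx(0.5)

    def test_all_zero_flagged_degenerate(self):
        m = compute_metrics(np.zeros(3))
        assert m["degenerate"]
        for k in ("FA", "T", "AD", "RD", "WL", "WP"):
            assert m[k] == 0.0

    @given(st.lists(st.floats(1e-6, 1e-2), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_westin_trace_identity(self, evals):
        l = np.sort(np.asarray(evals))[::-1]
        m = compute_metrics(l, "trace")
        ws = 3 * l[2] / m["T"]
        assert m["WL"] + m["WP"] + ws == pytest.approx(1.0, abs=1e-12)

    def test_conventions_agree_on_degenerate_shapes(self):
        for l in ([1.0, 0.5, 0.5], [1.0, 1.0, 0.0], [1.0, 0.0, 0.0]):
            a = compute_metrics(np.array(l), "trace")
            b = compute_metrics(np.array(l), "lambda1")
            if l[1] == l[2]:  # prolate family: WP = 0 both ways
                assert a["WP"] == b["WP"] == 0.0
            if l == [1.0, 1.0, 0.0]:
                assert a["WL"] == b["WL"] == 0.0

    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1e-3, 2e-3, 0.5e-3]))

    def test_rotation_invariance_through_full_fit(self, rng):
        # rotating tensor AND gradient table leaves all metrics unchanged
        sch = make_scheme(6, 32)
        ev = np.array([1.2e-3, 0.4e-3, 0.2e-3])
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        D = np.diag(ev)
        Drot = Q @ D @ Q.T
        from tbikit.scheme import AcquisitionScheme
        sch_rot = AcquisitionScheme(sch.b_values, sch.directions @ Q.T, sch.n_b0)
        ms = []
        for Dx, sx in ((D, sch), (Drot, sch_rot)):
            S = synthesize_dwi(tensor_to_components(Dx)[None], sx, snr=np.inf)
            c0, z0 = fit_tensor_loglinear(S, sx)
            c, z, _ = fit_tensor_nonlinear(S, sx, c0, z0)
            w, _, _ = eigensystem(c)
            ms.append(compute_metrics(w))
        for k in ("FA", "T", "AD", "RD", "WL", "WP"):
            assert ms[0][k] == pytest.approx(ms[1][k], abs=1e-8)


class TestTensorModelAPI:
    def test_fit_returns_results_with_metrics_and_summary(self, scheme, rng):
        D, ev = random_tensors(rng, 8)
        comps = tensor_to_components(D)
        S = synthesize_dwi(comps, scheme, s0=200.0, snr=np.inf)
        from tbikit.dti import TensorModel
        res = TensorModel(scheme, S).fit()
        assert res.converged.all()
        np.testing.assert_allclose(res.components, comps, rtol=1e-7, atol=1e-12)
        m = res.metrics()
        np.testing.assert_allclose(m["T"], ev.sum(axis=1), rtol=1e-7)
        np.testing.assert_allclose(res.predicted_signals(), S, rtol=1e-7)
        text = res.summary()
        assert "converged" in text and "mean FA" in text

    def test_mask_restricts_fitting(self, scheme):
        comps = np.tile([0.7e-3, 0.2e-3, 0.2e-3, 0, 0, 0], (4, 1))
        S = synthesize_dwi(comps, scheme, s0=100.0, snr=np.inf)
        from tbikit.dti import TensorModel
        mask = np.array([True, False, True, False])
        res = TensorModel(scheme, S).fit(mask=mask)
        assert np.all(res.components[~mask] == 0)
        assert np.all(res.components[mask, 0] > 0)

    def test_volume_count_mismatch_rejected(self, scheme):
        from tbikit.dti import TensorModel
        with pytest.raises(ValueError):
            TensorModel(scheme, np.ones((3, scheme.n_volumes + 1)))


class TestMetricMaps:
    def test_noise_free_phantom_fa_matches_closed_form(self, scheme):
        spec = PhantomSpec(grid_shape=(26, 22, 5))
        field = build_tensor_phantom(spec, "sham")
        dwi = synthesize_dwi(field, scheme, snr=np.inf)
        maps = metric_maps(dwi, scheme)
        wm_fa = float(fa_from_eigenvalues(np.array(spec.wm_eigenvalues)))
        gm_fa = float(fa_from_eigenvalues(np.array(spec.gm_eigenvalues)))
        from tbikit.phantom import WHITE_MATTER_ROIS
        for roi, expected in (("Optic Tract_Left", wm_fa), ("Cortex_Left", gm_fa)):
            got = maps["FA"][field.roi_mask(roi)]
            assert np.abs(got - expected).max() < 1e-6

    def test_all_background_volume_masks_out(self, scheme):
        dwi = np.zeros((4, 4, 2, scheme.n_volumes))
        maps = metric_maps(dwi, scheme)
        for k in ("FA", "T", "AD", "RD", "WL", "WP"):
            assert np.all(maps[k] == 0)
        assert not maps["mask"].any()

    def test_injured_phantom_lowers_roi_fa_by_closed_form(self, scheme):
        effects = {("Optic Tract_Left", 0): 0.8,
                   ("Optic Tract_Left", 1): 1.25,
                   ("Optic Tract_Left", 2): 1.25}
        spec = PhantomSpec(grid_shape=(26, 22, 5), injury_effects=effects)
        sham = build_tensor_phantom(spec, "sham")
        injured = build_tensor_phantom(spec, "injured")
        diff_expected = (
            float(fa_from_eigenvalues(np.array(spec.wm_eigenvalues)
                                      * [0.8, 1.25, 1.25]))
            - float(fa_from_eigenvalues(np.array(spec.wm_eigenvalues))))
        mask = sham.roi_mask("Optic Tract_Left")
        fas = []
        for field in (injured, sham):
            dwi = synthesize_dwi(field, scheme, snr=np.inf)
            fas.append(metric_maps(dwi, scheme)["FA"][mask].mean())
        assert fas[0] - fas[1] == pytest.approx(diff_expected, abs=1e-6)
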
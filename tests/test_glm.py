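"""Paradigm construction, HRF, GLM fit and cluster inference."""

import numpy as np
import pytest
from scipy import stats

from cordbold import synth
from cordbold.glm import (
    HRFParams,
    Paradigm,
    build_design_matrix,
    build_paradigm_boxcar,
    cluster_threshold,
    convolve_task,
    double_gamma_hrf,
    fit_glm,
    smooth_volume,
)


class TestParadigm:
    def test_study_design_gives_330_samples_150_active(self):
        box = build_paradigm_boxcar(Paradigm())
        assert box.size == 330
        assert box.sum() == 150  # five 30 s active segments at TR 1 s

    def test_active_start_small_case(self):
        box = build_paradigm_boxcar(
            Paradigm(n_segments=2, segment_duration=10, tr=2, start_state="active")
        )
        assert np.array_equal(box, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])

    @pytest.mark.parametrize("n_segments,duration,tr", [(11, 30, 1), (7, 24, 2), (4, 15, 3)])
    def test_boxcar_sum_counting_identity(self, n_segments, duration, tr):
        p = Paradigm(n_segments=n_segments, segment_duration=duration, tr=tr)
        box = build_paradigm_boxcar(p)
        n_active = n_segments // 2  # starting at rest
        assert box.sum() == n_active * duration / tr

    def test_non_integer_segment_length_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            Paradigm(segment_duration=10.5, tr=1.0)


class TestHrf:
    def test_peak_between_4_and_7_seconds(self):
        tr = 0.1
        h = double_gamma_hrf(tr)
        assert 4.0 <= np.argmax(h) * tr <= 7.0

    def test_zero_at_onset_and_single_sign_change(self):
        h = double_gamma_hrf(0.5)
        assert h[0] == 0.0
        signs = np.sign(h[np.abs(h) > 1e-12])
        assert (np.diff(signs) != 0).sum() == 1  # positive lobe then undershoot

    def test_unit_peak_normalization(self):
        assert double_gamma_hrf(1.0).max() == pytest.approx(1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HRFParams(peak_shape=-1)


class TestConvolution:
    def test_zero_boxcar_gives_zero_regressor(self):
        h = double_gamma_hrf(1.0)
        assert np.allclose(convolve_task(np.zeros(100), h), 0.0)

    def test_impulse_reproduces_kernel(self):
        h = double_gamma_hrf(1.0)
        box = np.zeros(100)
        box[0] = 1.0
        out = convolve_task(box, h)
        assert np.allclose(out[: h.size], h)

    def test_sustained_boxcar_approaches_kernel_sum(self):
        h = double_gamma_hrf(1.0)
        out = convolve_task(np.ones(200), h)
        assert out[-1] == pytest.approx(h.sum(), rel=1e-9)

    def test_kernel_longer_than_run_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            convolve_task(np.ones(10), np.ones(20))


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(6, 6, 4))
        assert np.array_equal(smooth_volume(img, 0.0, (2.0, 2.0, 2.0)), img)

    def test_mean_preserved_with_reflective_boundaries(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(10, 10, 6))
        sm = smooth_volume(img, 6.0, (2.3, 2.3, 2.3), mode="isotropic3d")
        assert sm.mean() == pytest.approx(img.mean(), rel=1e-9)

    def test_delta_response_matches_sampled_gaussian(self):
        img = np.zeros((41, 41, 1))
        img[20, 20, 0] = 1.0
        fwhm, vox = 6.0, 2.3
        sm = smooth_volume(img, fwhm, (vox, vox, vox), mode="inplane")
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        # inside the kernel support the response ratio is the sampled Gaussian
        x = np.arange(-4, 5)
        expected = np.exp(-(x**2) / (2 * sigma_vox**2))
        profile = sm[16:25, 20, 0] / sm[20, 20, 0]
        assert np.allclose(profile, expected, atol=1e-4)

    def test_inplane_mode_does_not_mix_slices(self):
        img = np.zeros((9, 9, 3))
        img[:, :, 1] = 1.0
        sm = smooth_volume(img, 6.0, (2.0, 2.0, 2.0), mode="inplane")
        assert np.allclose(sm[:, :, 0], 0.0) and np.allclose(sm[:, :, 2], 0.0)


class TestFit:
    def test_noiseless_phantom_recovers_percent_signal(self, noiseless_bold):
        run, roi = noiseless_bold
        design = build_design_matrix(run.paradigm)
        stat = fit_glm(run.data, design, voxel_dims=run.voxel_dims)
        assert np.allclose(stat.percent_signal[roi], 2.0, atol=1e-6)
        assert np.allclose(stat.percent_signal[~roi], 0.0, atol=1e-6)
        assert stat.dof == run.data.shape[-1] - design.matrix.shape[1]

    def test_constant_shift_changes_only_intercept(self, noiseless_bold):
        run, _ = noiseless_bold
        design = build_design_matrix(run.paradigm)
        a = fit_glm(run.data, design)
        b = fit_glm(run.data + 500.0, design)
        assert np.allclose(a.beta, b.beta, atol=1e-8)

    def test_null_noise_z_is_standard_normal(self):
        rng = np.random.default_rng(0)
        p = Paradigm(n_segments=11, segment_duration=10)
        data = rng.normal(0, 1, (22, 22, 22, 110))
        stat = fit_glm(data, build_design_matrix(p))
        z = stat.z.ravel()
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_rank_deficient_design_rejected_naming_columns(self):
        p = Paradigm(n_segments=4, segment_duration=10)
        motion = np.zeros((40, 6))
        motion[:, 0] = np.arange(40)
        motion[:, 1] = 2 * np.arange(40)  # collinear with tx
        with pytest.raises(ValueError, match="collinear"):
            build_design_matrix(p, motion=motion)

    def test_z_monotone_in_beta_at_fixed_variance(self):
        p = Paradigm(n_segments=4, segment_duration=10)
        design = build_design_matrix(p)
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 1, 40)
        task = design.task_regressor
        data = np.stack(
            [100 + amp * task + noise for amp in (0.0, 0.5, 1.0, 2.0)]
        ).reshape(4, 1, 1, 40)
        stat = fit_glm(data, design)
        z = stat.z.ravel()
        assert np.all(np.diff(z) > 0)


class TestClusterInference:
    def test_subthreshold_map_gives_empty_result(self):
        rng = np.random.default_rng(2)
        p = Paradigm(n_segments=4, segment_duration=10)
        run = rng.normal(0, 1, (6, 6, 6, 40))
        stat = fit_glm(run, build_design_matrix(p))
        stat.z[:] = 1.0
        res = cluster_threshold(stat, z_threshold=3.1, alpha=0.05, n_permutations=20, rng=0)
        assert not res.active_mask.any() and res.clusters == ()

    def test_strong_signal_cluster_overlaps_roi(self):
        roi = np.zeros((12, 12, 8), dtype=bool)
        roi[3:8, 3:8, 2:6] = True
        spec = synth.BoldPhantomSpec(
            volume_shape=(12, 12, 8), active_rois=((roi, 2.0),), noise_sd=10.0,
            n_segments=11, segment_duration=10, seed=3,
        )
        run = synth.make_bold_phantom(spec)
        design = build_design_matrix(run.paradigm, motion=run.motion)
        stat = fit_glm(run.data, design, voxel_dims=run.voxel_dims)
        res = cluster_threshold(stat, alpha=0.05, n_permutations=200, rng=0)
        inter = (res.active_mask & roi).sum()
        dice = 2 * inter / (res.active_mask.sum() + roi.sum())
        assert dice > 0.5

    def test_cluster_result_invariant_to_intensity_scaling(self):
        roi = np.zeros((10, 10, 6), dtype=bool)
        roi[3:7, 3:7, 2:5] = True
        spec = synth.BoldPhantomSpec(
            volume_shape=(10, 10, 6), active_rois=((roi, 1.5),), noise_sd=12.0,
            n_segments=11, segment_duration=10, seed=8,
        )
        run = synth.make_bold_phantom(spec)
        design = build_design_matrix(run.paradigm, motion=run.motion)
        a = fit_glm(run.data, design)
        b = fit_glm(run.data * 3.0, design)
        assert np.allclose(a.z, b.z, atol=1e-8)
        res_a = cluster_threshold(a, alpha=0.05, n_permutations=100, rng=1)
        res_b = cluster_threshold(b, alpha=0.05, n_permutations=100, rng=1)
        assert np.array_equal(res_a.active_mask, res_b.active_mask)

    def test_permutation_controls_familywise_error(self):
        # null runs: fraction with any surviving cluster stays at/below alpha
        hits = 0
        n_sim, alpha = 40, 0.05
        for i in range(n_sim):
            spec = synth.BoldPhantomSpec(
                volume_shape=(10, 10, 8), active_rois=(), noise_sd=10.0,
                motion_amplitude=0.0, n_segments=11, segment_duration=10, seed=2000 + i,
            )
            run = synth.make_bold_phantom(spec)
            stat = fit_glm(run.data, build_design_matrix(run.paradigm))
            res = cluster_threshold(
                stat, alpha=alpha, n_permutations=100, rng=np.random.default_rng(i)
            )
            hits += bool(res.clusters)
        # binomial 97.5% upper bound at p=alpha, n=40
        assert hits / n_sim <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_sim)

    def test_rft_p_values_monotone_in_cluster_size(self):
        roi = np.zeros((12, 12, 8), dtype=bool)
        roi[3:9, 3:9, 2:6] = True
        spec = synth.BoldPhantomSpec(
            volume_shape=(12, 12, 8), active_rois=((roi, 2.5),), noise_sd=8.0,
            n_segments=11, segment_duration=10, seed=4,
        )
        run = synth.make_bold_phantom(spec)
        stat = fit_glm(run.data, build_design_matrix(run.paradigm, motion=run.motion))
        res = cluster_threshold(stat, alpha=0.9, method="rft")
        sizes = [c.size_voxels for c in res.clusters]
        ps = [c.corrected_p for c in res.clusters]
        order = np.argsort(sizes)
        assert all(np.diff(np.array(ps)[order]) <= 1e-12)
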
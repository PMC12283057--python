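import numpy as np
import pytest
from scipy import ndimage, stats as sps

from dualswift.phantom import IRFParams, Paradigm, response_curve
from dualswift.stats import (
    StatsParams,
    build_design,
    compare_peak_latencies,
    extract_clusters,
    extract_timecourse,
    fit_glm,
    group_inference,
    tfce,
)


class TestDesign:
    def test_default_length_and_columns(self):
        d = build_design(Paradigm(), IRFParams(), 3.0, 248)
        assert d.shape == (248, 2)
        assert np.allclose(d[:, 1], 1.0)
        assert d[:, 0].max() == pytest.approx(1.0, abs=0.01)

    def test_zero_paradigm_zero_regressor(self):
        d = build_design(Paradigm(n_blocks=0), IRFParams(), 3.0, 20)
        assert not d[:, 0].any()

    def test_onset_to_peak_matches_fine_grid_oracle(self):
        d = build_design(Paradigm(), IRFParams(), 3.0, 248)
        fine = response_curve(Paradigm(), IRFParams(), 0.1)
        t_coarse = 3.0 * np.argmax(d[:, 0] >= 0.95)
        t_fine = 0.1 * np.argmax(fine >= 0.95)
        assert abs(t_coarse - t_fine) <= 1.5  # within volume_tr / 2

    def test_response_latency_shifts_regressor(self):
        d0 = build_design(Paradigm(), IRFParams(), 3.0, 248)
        d9 = build_design(Paradigm(), IRFParams(), 3.0, 248, response_latency=9.0)
        assert np.argmax(d9[:, 0] >= 0.5) - np.argmax(d0[:, 0] >= 0.5) == 3


class TestGLM:
    def _series(self, signal, noise_sd, n_vox=64, seed=0, t_len=248):
        rng = np.random.default_rng(seed)
        data = 100.0 + signal[:, None] + noise_sd * rng.standard_normal((t_len, n_vox))
        return data.reshape(t_len, 4, 4, n_vox // 16)

    def test_beta_is_one_for_exact_regressor_voxel(self):
        d = build_design(Paradigm(), IRFParams(), 3.0, 248)
        data = self._series(d[:, 0], 0.0)
        res = fit_glm(data, d, ar_order=0)
        assert np.allclose(res.beta, 1.0, atol=1e-8)
        assert np.all(res.z >= 38.0 - 1e-6)  # zero-variance voxels capped

    def test_roi_z_matches_analytic_expectation(self):
        d = build_design(Paradigm(), IRFParams(), 3.0, 248)
        task = d[:, 0]
        data = self._series(task, 1.0, n_vox=256, seed=3)
        res = fit_glm(data, d, ar_order=0)
        expect = np.linalg.norm(task - task.mean())  # CNR 1 per volume
        assert res.z.mean() == pytest.approx(expect, rel=0.2)

    def test_null_with_shifted_regressor(self):
        d = build_design(Paradigm(), IRFParams(), 3.0, 248)
        d_null = d.copy()
        d_null[:, 0] = np.roll(d[:, 0], 19)  # half a block period
        rng = np.random.default_rng(5)
        data = 100.0 + rng.standard_normal((248, 10, 10, 10))
        res = fit_glm(data, d_null, ar_order=0)
        assert abs(res.z.mean()) < 0.1

    def test_intensity_rescale_invariance(self):
        d = build_design(Paradigm(), IRFParams(), 3.0, 248)
        rng = np.random.default_rng(6)
        data = 50.0 + rng.standard_normal((248, 4, 4, 4))
        z1 = fit_glm(data, d).z
        z2 = fit_glm(3.0 * data + 17.0, d).z
        assert np.allclose(z1, z2, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        d = np.ones((40, 2))
        with pytest.raises(ValueError):
            fit_glm(np.random.default_rng(0).standard_normal((40, 3, 3, 3)), d)


class TestClusters:
    def test_planted_block(self):
        z = np.zeros((10, 10, 10))
        z[3:6, 3:6, 3:6] = 5.0
        table = extract_clusters(z)
        assert len(table) == 1
        assert table.loc[0, "n_voxels"] == 27
        assert table.loc[0, "centroid_x"] == pytest.approx(4.0)

    def test_corner_touching_blocks_are_separate(self):
        z = np.zeros((10, 10, 10))
        z[2:4, 2:4, 2:4] = 5.0
        z[4:6, 4:6, 4:6] = 5.0  # touches only at the corner voxel diagonal
        table = extract_clusters(z)
        assert len(table) == 2

    def test_sorted_by_size(self):
        z = np.zeros((12, 12, 12))
        z[1:2, 1:2, 1:2] = 4.0
        z[5:9, 5:9, 5:9] = 4.0
        table = extract_clusters(z)
        assert table.loc[0, "n_voxels"] == 64

    def test_nonfinite_rejected(self):
        z = np.zeros((4, 4, 4))
        z[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            extract_clusters(z)


def tfce_oracle(stat, params):
    """Independent per-voxel threshold loop (no shared labelling across
    voxels; recomputes the component for every voxel and height)."""
    peak = stat.max()
    dh = params.tfce_dh * peak
    heights = np.arange(dh, peak + 0.5 * dh, dh)
    out = np.zeros_like(stat)
    for idx in np.argwhere(stat > 0):
        v = tuple(idx)
        acc = 0.0
        for h in heights:
            if stat[v] < h:
                break
            labels, _ = ndimage.label(stat >= h)
            extent = (labels == labels[v]).sum()
            acc += extent**params.tfce_e * h**params.tfce_h
        out[v] = acc * dh
    return out


class TestTFCE:
    def test_single_voxel_closed_form(self):
        # isolated voxel of height 1: integral of h^2 dh from 0 to 1 = 1/3
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 1.0
        out = tfce(stat)
        assert out[2, 2, 2] == pytest.approx(1.0 / 3.0, rel=0.02)
        assert out.sum() == pytest.approx(out[2, 2, 2])

    def test_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(0)
        params = StatsParams(tfce_dh=0.05)
        for _ in range(3):
            stat = np.maximum(rng.standard_normal((8, 8, 8)), 0.0)
            assert np.allclose(tfce(stat, params=params), tfce_oracle(stat, params), atol=1e-9)

    def test_monotone_in_voxel_height(self):
        rng = np.random.default_rng(1)
        params = StatsParams(tfce_dh=0.05)
        stat = np.maximum(rng.standard_normal((8, 8, 8)), 0.0)
        base = tfce(stat, params=params)
        bumped = stat.copy()
        v = tuple(np.argwhere(stat > 0)[0])
        bumped[v] += 0.5
        out = tfce(bumped, params=params)
        assert np.all(out >= base - 1e-6 * base.max())

    def test_flat_zero_map(self):
        assert not tfce(np.zeros((6, 6, 6))).any()


class TestGroupInference:
    def test_exhaustive_flips_and_p_grid(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((8, 6, 6, 6))
        res = group_inference(maps, params=StatsParams(tfce_dh=0.05), seed=0)
        assert res["n_permutations"] == 256
        assert np.allclose((res["p_fwe"] * 256) % 1.0, 0.0)
        assert res["p_fwe"].min() >= 1.0 / 256.0

    def test_planted_effect_detected_background_clean(self):
        rng = np.random.default_rng(1)
        maps = 0.5 * rng.standard_normal((8, 8, 8, 8))
        maps[:, 2:5, 2:5, 2:5] += 2.0
        res = group_inference(maps, params=StatsParams(tfce_dh=0.05), seed=0)
        sig = res["significant"]
        assert sig[2:5, 2:5, 2:5].all()
        # TFCE support may spill at most one voxel beyond the planted block
        spill = sig & ~ndimage.binary_dilation(
            np.pad(np.ones((3, 3, 3), bool), ((2, 3),) * 3)
        )
        assert not spill.any()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            group_inference(np.zeros((1, 4, 4, 4)))


class TestTimecourse:
    def _series_from_curve(self, curve, mask_shape=(6, 6, 6), amp=0.01, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        roi = np.zeros(mask_shape, dtype=bool)
        roi[2:4, 2:4, 2:4] = True
        base = 200.0 * np.ones(mask_shape)
        data = base[None] * (1 + amp * roi[None] * curve[:, None, None, None])
        if noise:
            data = data + noise * rng.standard_normal(data.shape)
        return data, roi

    def test_constant_series_flat_curve(self):
        par = Paradigm()
        data, roi = self._series_from_curve(np.zeros(248))
        tc = extract_timecourse(data, roi, par, 3.0)
        assert np.allclose(tc["percent_change"], 0.0)

    def test_injected_amplitude_and_latency_recovered(self):
        par, irf = Paradigm(), IRFParams()
        r9 = response_curve(par, irf, 3.0, latency_shift=9.0)
        data, roi = self._series_from_curve(r9, amp=0.01, noise=0.05, seed=2)
        tc = extract_timecourse(data, roi, par, 3.0, irf=irf)
        assert tc["peak_value"] == pytest.approx(1.0, abs=0.2)
        r0 = response_curve(par, irf, 3.0)
        data0, _ = self._series_from_curve(r0, amp=0.01, noise=0.05, seed=3)
        tc0 = extract_timecourse(data0, roi, par, 3.0, irf=irf)
        assert tc["peak_latency"] - tc0["peak_latency"] == pytest.approx(9.0, abs=3.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_timecourse(
                np.ones((20, 4, 4, 4)), np.zeros((4, 4, 4), bool), Paradigm(), 3.0
            )


class TestLatencyComparison:
    def test_identical_vectors_guarded(self):
        with pytest.warns(UserWarning):
            res = compare_peak_latencies([9.0, 9.0, 9.0], [9.0, 9.0, 9.0])
        assert res["t"] == 0.0
        assert res["mean_difference"] == 0.0

    def test_sign_antisymmetry(self):
        a = [18.0, 17.0, 19.0, 18.5]
        b = [9.0, 10.0, 8.5, 9.5]
        r1 = compare_peak_latencies(a, b)
        r2 = compare_peak_latencies(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_power_at_printed_significance(self):
        # 8 subjects, true 9 s shift, 1.5 s jitter: p < 0.001 in >= 90% of
        # 200 simulated experiments
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            brain = 9.0 + 1.5 * rng.standard_normal(8)
            cord = 18.0 + 1.5 * rng.standard_normal(8)
            if compare_peak_latencies(cord, brain)["p"] < 0.001:
                hits += 1
        assert hits >= 180
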
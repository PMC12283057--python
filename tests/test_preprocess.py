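import numpy as np
import pytest

from dualswift.phantom import IRFParams, Paradigm, make_dual_phantom, response_curve
from dualswift.preprocess import (
    ComponentSet,
    MotionTrace,
    PreprocParams,
    center_of_mass_motion,
    classify_motion_components,
    decompose_components,
    dct_highpass_basis,
    edge_shell,
    highpass,
    prewhiten,
    regress_out,
    rigid_motion_correct,
)


def moving_series(n=16, n_vol=20, shift=(0, 0, 2), at=10, seed=0, noise=0.0):
    ph = make_dual_phantom(matrix_size=n, effect_size=(0, 0), seed=seed)
    rng = np.random.default_rng(seed)
    vol = ph.volumes[0]
    series = np.stack([vol] * n_vol)
    for t in range(at, n_vol):
        series[t] = np.roll(vol, shift, axis=(0, 1, 2))
    if noise:
        series = series + noise * rng.standard_normal(series.shape)
    return series, ph


class TestCenterOfMass:
    def test_static_series_zero_trace(self):
        series, _ = moving_series(shift=(0, 0, 0))
        trace = center_of_mass_motion(series)
        assert np.allclose(trace.com_displacement, 0.0)

    def test_injected_step_recovered(self):
        series, _ = moving_series(shift=(0, 0, 2), at=10)
        trace = center_of_mass_motion(series)
        assert np.allclose(trace.com_displacement[10:, 2], 2.0, atol=0.05)
        assert np.allclose(trace.com_displacement[:10], 0.0, atol=1e-9)

    def test_intensity_scale_invariance(self):
        series, _ = moving_series()
        a = center_of_mass_motion(series).com_displacement
        b = center_of_mass_motion(series * 7.3).com_displacement
        assert np.allclose(a, b)

    def test_all_zero_volume_rejected(self):
        series, _ = moving_series()
        series[4] = 0.0
        with pytest.raises(ValueError):
            center_of_mass_motion(series)


class TestRigidCorrection:
    def test_injected_translations_corrected(self):
        series, _ = moving_series(n_vol=16, shift=(1, 0, -2), at=6, noise=0.002)
        corrected, trace = rigid_motion_correct(series)
        residual = center_of_mass_motion(corrected)
        assert residual.max_displacement < 0.2
        # estimated motion matches the injection (registration shift is
        # reported as reference-minus-moving)
        assert np.allclose(np.abs(trace.rigid_translations[6:, 2]), 2.0, atol=0.2)

    def test_identity_on_static_series(self):
        series, _ = moving_series(shift=(0, 0, 0))
        corrected, _ = rigid_motion_correct(series)
        scale = np.ptp(series)
        assert np.max(np.abs(corrected - series)) < 1e-6 * scale

    def test_correction_reduces_relative_motion_summary(self):
        for shift in [(0, 0, 2), (2, 0, 0), (0, -2, 2)]:
            series, _ = moving_series(shift=shift, at=8, noise=0.002)
            corrected, _ = rigid_motion_correct(series)
            before = center_of_mass_motion(series).max_displacement
            after = center_of_mass_motion(corrected).max_displacement
            assert after < before


class TestICA:
    def test_planted_sources_recovered(self):
        rng = np.random.default_rng(0)
        shape, t_len = (12, 12, 12), 80
        m1 = np.zeros(shape); m1[2:5, 2:5, 2:5] = 1.0
        m2 = np.zeros(shape); m2[7:10, 7:10, 7:10] = 1.0
        tc1 = np.sin(np.arange(t_len) / 4.0)
        tc2 = np.sign(np.sin(np.arange(t_len) / 9.0))
        data = (
            tc1[:, None, None, None] * m1[None]
            + tc2[:, None, None, None] * m2[None]
            + 0.01 * rng.standard_normal((t_len,) + shape)
        )
        comps = decompose_components(data, n_components=2, seed=1)
        corr = np.abs(np.corrcoef(comps.timecourses.T, np.vstack([tc1, tc2]))[:2, 2:])
        # after sign/order matching each planted time course is recovered
        assert max(corr[0, 0], corr[1, 0]) > 0.95
        assert max(corr[0, 1], corr[1, 1]) > 0.95

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((30, 8, 8, 8))
        a = decompose_components(data, 5, seed=42)
        b = decompose_components(data, 5, seed=42)
        assert np.allclose(a.timecourses, b.timecourses)
        assert np.allclose(a.maps, b.maps)

    def test_too_many_components_reduced_with_warning(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 6, 6, 6))
        with pytest.warns(UserWarning, match="reducing"):
            comps = decompose_components(data, n_components=20, seed=0)
        assert comps.n_components == 9


def planted_components(n=12, t_len=60):
    """Fixture with known labels: a motion-locked time course, an edge-ring
    map, a clean interior signal, and a threshold-straddling case."""
    obj = np.zeros((n, n, n), dtype=bool)
    obj[2:-2, 2:-2, 2:-2] = True
    shell = edge_shell(obj, 1)
    motion_z = np.zeros(t_len)
    motion_z[t_len // 2 :] = 2.0
    trace = MotionTrace(com_displacement=np.column_stack(
        [np.zeros(t_len), np.zeros(t_len), motion_z]
    ))
    rng = np.random.default_rng(7)

    interior = np.zeros((n, n, n))
    interior[5:8, 5:8, 5:8] = 5.0
    ring = np.where(shell, 5.0, 0.0)
    half_edge = np.zeros((n, n, n))
    edge_vox = np.argwhere(shell)
    in_vox = np.argwhere(obj & ~shell)
    half_edge[tuple(edge_vox[:10].T)] = 5.0
    half_edge[tuple(in_vox[:10].T)] = 5.0

    tc_motion = motion_z - motion_z.mean()
    tc_rand = rng.standard_normal(t_len)
    tc_rand -= tc_rand.mean()
    # time course whose |r| with the z motion parameter sits at the 0.75
    # threshold (a hair below, so the strict ">" rule must leave it alone)
    resid = tc_rand - np.dot(tc_rand, tc_motion) / np.dot(tc_motion, tc_motion) * tc_motion
    u = tc_motion / np.linalg.norm(tc_motion)
    v = resid / np.linalg.norm(resid)
    r_tie = 0.75 * (1.0 - 1e-9)
    tc_075 = r_tie * u + np.sqrt(1 - r_tie**2) * v
    assert abs(abs(np.corrcoef(tc_075, motion_z)[0, 1]) - 0.75) < 1e-6

    maps = np.stack([interior, ring, interior, half_edge])
    tcs = np.column_stack([tc_motion, tc_rand, rng.standard_normal(t_len), tc_075])
    comps = ComponentSet(maps=maps, timecourses=tcs)
    expected = ["motion", "motion", "signal", "signal"]
    return comps, trace, obj, expected


class TestMotionClassifier:
    def test_planted_fixture_perfect_labels(self):
        comps, trace, obj, expected = planted_components()
        labels = classify_motion_components(comps, trace, obj)
        assert labels == expected

    def test_thresholds_are_strict(self):
        # |r| = 0.75 exactly and 50% edge voxels -> NOT motion
        comps, trace, obj, _ = planted_components()
        labels = classify_motion_components(comps, trace, obj)
        assert labels[3] == "signal"

    def test_empty_suprathreshold_map_fails_edge_rule(self):
        comps, trace, obj, _ = planted_components()
        comps.maps[2][:] = 0.0
        labels = classify_motion_components(comps, trace, obj)
        assert labels[2] == "signal"


class TestRegression:
    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((50, 6, 6, 6))
        regs = rng.standard_normal((50, 3))
        out = regress_out(data, regs)
        flat = out.reshape(50, -1)
        for j in range(3):
            r = regs[:, j] - regs[:, j].mean()
            corr = np.abs(r @ (flat - flat.mean(0))) / (
                np.linalg.norm(r) * np.linalg.norm(flat - flat.mean(0), axis=0)
            )
            assert corr.max() < 1e-10

    def test_no_regressors_is_identity(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 4, 4, 4))
        assert np.array_equal(regress_out(data, np.empty((20, 0))), data)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((40, 5, 5, 5))
        regs = rng.standard_normal((40, 2))
        once = regress_out(data, regs)
        twice = regress_out(once, regs)
        assert np.allclose(once, twice, atol=1e-10)


class TestHighpass:
    def test_linear_drift_removed(self):
        # 744 s series at 3 s TR, 0.01 Hz cutoff
        t = np.arange(248) * 3.0
        drift = (t - t.mean()) / t.max()
        out = highpass(drift[:, None, None, None] * np.ones((1, 2, 2, 2)), 3.0, 0.01)
        assert np.abs(out).max() < 0.05 * np.abs(drift).max()

    def test_passband_sinusoid_survives(self):
        t = np.arange(248) * 3.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = highpass(sig, 3.0, 0.01)
        assert np.linalg.norm(out - out.mean()) / np.linalg.norm(sig) > 0.99

    def test_task_fundamental_attenuation_is_measured(self):
        # the paradigm's fundamental (1/114 Hz) lies below the 0.01 Hz
        # cutoff; the filter attenuates the task regressor measurably but
        # leaves most of its energy (harmonics are in the passband)
        task = response_curve(Paradigm(), IRFParams(), 3.0)
        filtered = highpass(task, 3.0, 0.01)
        ratio = np.linalg.norm(filtered - filtered.mean()) / np.linalg.norm(task - task.mean())
        assert 0.55 < ratio < 0.9

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(np.zeros((20, 2, 2, 2)), 3.0, cutoff=0.2)

    def test_basis_frequencies_below_cutoff(self):
        basis = dct_highpass_basis(248, 3.0, 0.01)
        assert basis.shape[1] == 14  # k/1488 Hz < 0.01 -> k = 1..14


class TestPrewhitening:
    def _ar_series(self, phi, n_t=200, n_v=500, seed=0):
        rng = np.random.default_rng(seed)
        e = rng.standard_normal((n_t, n_v))
        x = np.zeros_like(e)
        for t in range(1, n_t):
            x[t] = phi * x[t - 1] + e[t]
        return x

    def test_white_noise_phi_near_zero(self):
        x = self._ar_series(0.0)
        _, _, phi = prewhiten(x, x, np.ones((200, 1)))
        assert abs(phi.mean()) < 0.05

    def test_ar1_coefficient_recovered(self):
        x = self._ar_series(0.4)
        _, _, phi = prewhiten(x, x, np.ones((200, 1)))
        assert phi.mean() == pytest.approx(0.4, abs=0.05)

    def test_whitened_residuals_are_white(self):
        x = self._ar_series(0.5, seed=1)
        yw, _, _ = prewhiten(x, x, np.ones((200, 1)))
        lag1 = (yw[1:] * yw[:-1]).sum(0) / (yw**2).sum(0)
        assert abs(lag1.mean()) < 0.05
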
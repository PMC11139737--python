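"""Phantom generation and dynamic-frame simulation against closed forms."""

import numpy as np
import pytest
from scipy.integrate import quad

from rb82dose.physics import FrameSchedule
from rb82dose.synthetic import (
    DEFAULT_ORGAN_NAMES,
    Component,
    LabelMap,
    OrganKinetics,
    OrganSpec,
    default_phantom,
    generate_phantom,
    noise_scale_for_cv,
    simulate_frames,
    true_activity,
)


class TestGeneratePhantom:
    def test_cubic_organ_volume(self):
        # 10x10x10 voxels at 2 mm isotropic -> 8.0 mL
        spec = OrganSpec(
            1, "cube", (Component("box", (10.5, 10.5, 10.5), (4.5, 4.5, 4.5)),), 0.01
        )
        lm, kin = generate_phantom(
            (24, 24, 24), [spec], seed=0, voxel_size_mm=(2.0, 2.0, 2.0)
        )
        assert np.count_nonzero(lm.voxels == 1) == 1000
        assert kin[0].volume_mL == pytest.approx(8.0)

    def test_same_seed_is_deterministic(self):
        lm1, kin1 = default_phantom(seed=7)
        lm2, kin2 = default_phantom(seed=7)
        assert np.array_equal(lm1.voxels, lm2.voxels)
        assert kin1 == kin2

    def test_default_legend_is_the_eleven_source_organs(self):
        lm, _ = default_phantom(seed=0)
        assert set(lm.legend.values()) == set(DEFAULT_ORGAN_NAMES)
        assert len(lm.legend) == 11

    def test_overlapping_organs_rejected(self):
        specs = [
            OrganSpec(1, "a", (Component("ellipsoid", (10, 10, 10), (4, 4, 4)),), 0.01),
            OrganSpec(2, "b", (Component("ellipsoid", (12, 10, 10), (4, 4, 4)),), 0.01),
        ]
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom((24, 24, 24), specs, seed=0)

    def test_organ_volumes_match_voxel_counts(self):
        lm, kin = default_phantom(seed=2)
        for k in kin:
            n = np.count_nonzero(lm.organ_mask(k.organ_id))
            assert k.volume_mL == pytest.approx(n * lm.voxel_volume_mL)

    def test_activity_never_exceeds_injection(self):
        # conservation headroom: total biological activity stays below the
        # injected activity at all times (no excretion pathway exists)
        injected = 400.0
        lm, kin = default_phantom(seed=5, injected_MBq=injected)
        t = np.linspace(0, 420, 421)
        total_kBq = sum(k.concentration(t) * k.volume_mL for k in kin)
        assert np.max(total_kBq) <= injected * 1000.0 * (1 + 1e-9)


class TestTrueActivity:
    def test_one_half_life(self):
        kin = OrganKinetics(1, "o", 1.0, 0.0, 0.0, 0.0, 1.0)
        lam = np.log(2) / 76.0
        assert true_activity(kin, 76.0, lam) == pytest.approx(0.5)

    def test_time_zero_is_amplitude_sum(self):
        kin = OrganKinetics(1, "o", 3.0, -1.0, 0.0, 0.05, 1.0)
        assert true_activity(kin, 0.0, 0.01) == pytest.approx(2.0)

    def test_integral_is_mean_lifetime(self):
        kin = OrganKinetics(1, "o", 1.0, 0.0, 0.0, 0.0, 1.0)
        lam = np.log(2) / 76.0
        oracle, _ = quad(lambda t: true_activity(kin, t, lam), 0, np.inf)
        assert oracle == pytest.approx(1.0 / lam, rel=1e-9)

    def test_negative_curve_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            OrganKinetics(1, "o", 1.0, -2.0, 0.0, 0.05, 1.0)


def _single_organ_setup(a1, a2, mu1, mu2):
    spec = OrganSpec(
        1, "organ", (Component("ellipsoid", (7.5, 7.5, 7.5), (5.5, 5.5, 5.5)),), 0.0
    )
    lm, _ = generate_phantom((16, 16, 16), [spec], seed=0)
    vol = lm.organ_volume_mL(1)
    kin = OrganKinetics(1, "organ", a1, a2, mu1, mu2, vol)
    return lm, kin


class TestSimulateFrames:
    def test_constant_curve_survives_decay_correction(self, schedule, nuclide):
        # pure physical decay of a constant source: correction must cancel it
        lm, kin = _single_organ_setup(5.0, 0.0, 0.0, 0.0)
        dyn = simulate_frames(lm, [kin], schedule, nuclide, noise_scale=0.0)
        organ_vals = dyn.voxels[lm.organ_mask(1), :]
        np.testing.assert_allclose(organ_vals, 5.0, rtol=1e-12)

    def test_noiseless_frames_match_analytic_averages(self, schedule, nuclide, lam):
        lm, kin = _single_organ_setup(10.0, -10.0, 1e-4, 0.04)
        dyn = simulate_frames(lm, [kin], schedule, nuclide, noise_scale=0.0)
        expected = kin.frame_average_corrected(schedule, lam)
        means = dyn.voxels[lm.organ_mask(1), :].mean(axis=0)
        np.testing.assert_allclose(means, expected, rtol=1e-10)

    def test_analytic_frame_average_against_quadrature(self, schedule, lam):
        # independent oracle for the closed-form frame average
        _, kin = _single_organ_setup(10.0, -10.0, 1e-4, 0.04)
        from rb82dose.physics import frame_decay_correction_factor

        for i, (t1, t2) in enumerate(schedule.frames):
            avg, _ = quad(lambda t: true_activity(kin, t, lam), t1, t2)
            avg /= t2 - t1
            expected = avg * frame_decay_correction_factor((t1, t2), lam)
            assert kin.frame_average_corrected(schedule, lam)[i] == pytest.approx(
                expected, rel=1e-9
            )

    def test_poisson_noise_within_sampling_error(self, schedule, nuclide, lam):
        lm, kin = _single_organ_setup(20.0, -20.0, 0.0, 0.04)
        n_vox = int(np.count_nonzero(lm.organ_mask(1)))
        assert n_vox >= 600
        ns = 0.5
        noiseless = kin.frame_average_corrected(schedule, lam)
        dyn = simulate_frames(lm, [kin], schedule, nuclide, noise_scale=ns, seed=11)
        means = dyn.voxels[lm.organ_mask(1), :].mean(axis=0)
        se = np.sqrt(noiseless / (ns * schedule.durations * n_vox))
        assert np.all(np.abs(means - noiseless) < 3.0 * se)

    def test_noise_is_seed_deterministic(self, schedule, nuclide):
        lm, kin = _single_organ_setup(20.0, -20.0, 0.0, 0.04)
        d1 = simulate_frames(lm, [kin], schedule, nuclide, noise_scale=0.2, seed=3)
        d2 = simulate_frames(lm, [kin], schedule, nuclide, noise_scale=0.2, seed=3)
        assert np.array_equal(d1.voxels, d2.voxels)

    def test_negative_noise_scale_rejected(self, schedule, nuclide):
        lm, kin = _single_organ_setup(1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            simulate_frames(lm, [kin], schedule, nuclide, noise_scale=-1.0)


def test_noise_scale_calibration(schedule, lam):
    # the calibrated scale reproduces the requested mean per-frame CV
    _, kin = _single_organ_setup(30.0, -30.0, 0.0, 0.03)
    n_vox = 500
    ns = noise_scale_for_cv(kin, schedule, lam, n_vox, target_cv=0.05)
    v = kin.frame_average_corrected(schedule, lam)
    cv = 1.0 / np.sqrt(v * ns * schedule.durations * n_vox)
    assert np.mean(cv) == pytest.approx(0.05, rel=1e-9)


def test_labelmap_legend_must_match_voxels():
    voxels = np.zeros((4, 4, 4), dtype=int)
    voxels[0, 0, 0] = 1
    with pytest.raises(ValueError, match="absent"):
        LabelMap(voxels, {1: "a", 2: "ghost"}, (4.0, 4.0, 4.0))
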
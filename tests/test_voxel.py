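"""Voxel TIA maps, dose maps and organ-dose extraction."""

import numpy as np
import pytest

from rb82dose.physics import FrameSchedule, NuclideSpec, decay_constant
from rb82dose.synthetic import DynamicImage, LabelMap
from rb82dose.voxel import (
    DoseMap,
    TIAMap,
    dose_map_kernel,
    dose_map_local,
    gaussian_kernel,
    organ_dose_from_map,
    tail_rate,
    voxel_tia_map,
)

LAM = decay_constant(NuclideSpec("Rb-82", 76.0))


class TestTailRate:
    def test_one_half_life_between_points(self):
        assert tail_rate(2.0, 1.0, 269.0, 345.0, LAM) == pytest.approx(
            np.log(2) / 76.0
        )

    def test_flat_voxel_falls_back_to_physical(self):
        assert tail_rate(1.0, 1.0, 225.0, 345.0, LAM) == LAM

    def test_empty_voxel_falls_back(self):
        assert tail_rate(1.0, 0.0, 225.0, 345.0, LAM) == LAM
        assert tail_rate(0.0, 0.0, 225.0, 345.0, LAM) == LAM

    def test_slower_than_physics_is_clamped(self):
        slow = tail_rate(1.05, 1.0, 225.0, 345.0, LAM)
        assert slow == LAM

    def test_bad_times_rejected(self):
        with pytest.raises(ValueError):
            tail_rate(2.0, 1.0, 345.0, 225.0, LAM)


def _single_voxel_image(schedule, corrected_values, voxel_mm=10.0):
    vox = np.asarray(corrected_values, dtype=float).reshape(1, 1, 1, -1)
    return DynamicImage(vox, (voxel_mm,) * 3, schedule, decay_corrected=True)


class TestVoxelTiaMap:
    def test_two_frame_toy_hand_value(self):
        # physical values 4 and 2 kBq/mL at midpoints 15 and 45 s:
        # trapezoid 30*3 = 90, rectangle edge 15*4 = 60,
        # tail 2/(ln2/30) = 86.5618 -> 236.5618 kBq*s/mL in a 1 mL voxel
        sch = FrameSchedule(frames=((0, 30), (30, 60)))
        corrected = np.array([4.0, 2.0]) * np.exp(LAM * np.array([15.0, 45.0]))
        dyn = _single_voxel_image(sch, corrected)
        tmap = voxel_tia_map(dyn, LAM, injected_MBq=1.0)
        expected = (90.0 + 60.0 + 2.0 * 30.0 / np.log(2)) / 1000.0 / 3600.0
        assert tmap.values[0, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_constant_corrected_value_recovers_mean_lifetime(self, schedule):
        # a purely physically decaying source: exact integral c/lam, the
        # discretized estimate must land within 2%
        c = 7.0
        dyn = _single_voxel_image(schedule, np.full(7, c))
        tmap = voxel_tia_map(dyn, LAM, injected_MBq=1.0)
        exact = c / LAM / 1000.0 / 3600.0  # 1 mL voxel
        assert tmap.values[0, 0, 0] == pytest.approx(exact, rel=0.02)
        assert tmap.tail_fallback_fraction == 0.0

    def test_zero_image_gives_zero_map(self, schedule):
        dyn = _single_voxel_image(schedule, np.zeros(7))
        tmap = voxel_tia_map(dyn, LAM, injected_MBq=1.0)
        assert np.all(tmap.values == 0.0)

    def test_too_few_frames_rejected(self):
        sch = FrameSchedule(frames=((0, 30),))
        dyn = _single_voxel_image(sch, [1.0])
        with pytest.raises(ValueError, match="2 frames"):
            voxel_tia_map(dyn, LAM, injected_MBq=1.0)

    def test_physical_bound_per_voxel(self, noiseless_study, lam):
        # no voxel can out-integrate its peak decay-corrected concentration
        # decaying purely physically
        dyn = noiseless_study["dynamic"]
        injected = noiseless_study["injected_MBq"]
        tmap = voxel_tia_map(dyn, lam, injected)
        c_max = dyn.voxels.max(axis=-1)  # kBq/mL, decay-corrected
        bound = c_max / lam * dyn.voxel_volume_mL / 1000.0 / 3600.0 / injected
        assert np.all(tmap.values <= bound * (1 + 1e-9))


class TestDoseMapLocal:
    def _unit_tia(self, voxel_mm=2.0):
        values = np.ones((1, 1, 1))
        return TIAMap(values, (voxel_mm,) * 3, 0.0)

    def test_hand_computed_unit_dose(self):
        # 1 MBq*h in an 8 mm^3 voxel at 1 MeV/decay:
        # 3.6e9 * 1.602e-13 J / 8e-6 kg = 72.09 Gy
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.0)
        dose = dose_map_local(self._unit_tia(), nuc)
        assert dose.values[0, 0, 0] / 1e6 == pytest.approx(72.09, rel=1e-3)

    def test_zero_tia_gives_zero_dose(self):
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.0)
        tia = TIAMap(np.zeros((2, 2, 2)), (2.0,) * 3, 0.0)
        assert np.all(dose_map_local(tia, nuc).values == 0.0)

    def test_density_halves_dose(self):
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.0)
        d1 = dose_map_local(self._unit_tia(), nuc, density_g_per_mL=1.0)
        d2 = dose_map_local(self._unit_tia(), nuc, density_g_per_mL=2.0)
        np.testing.assert_allclose(d2.values, d1.values / 2.0)

    def test_linear_in_energy(self):
        n1 = NuclideSpec("a", 76.0, mean_energy_per_decay_MeV=1.0)
        n2 = NuclideSpec("b", 76.0, mean_energy_per_decay_MeV=2.5)
        d1 = dose_map_local(self._unit_tia(), n1)
        d2 = dose_map_local(self._unit_tia(), n2)
        np.testing.assert_allclose(d2.values, 2.5 * d1.values)


class TestDoseMapKernel:
    def test_delta_kernel_equals_local_mode(self):
        rng = np.random.default_rng(0)
        tia = TIAMap(rng.uniform(0, 1, (8, 8, 8)), (4.0,) * 3, 0.0)
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.41)
        delta = np.ones((1, 1, 1))
        local = dose_map_local(tia, nuc)
        kern = dose_map_kernel(tia, delta, nuc)
        np.testing.assert_allclose(kern.values, local.values, rtol=1e-10)

    def test_uniform_medium_matches_local(self):
        # away from edges a normalized kernel redistributes energy without
        # changing the uniform dose level
        tia = TIAMap(np.full((16, 16, 16), 0.01), (4.0,) * 3, 0.0)
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.41)
        k = gaussian_kernel(sigma_vox=1.0, radius=3)
        local = dose_map_local(tia, nuc)
        kern = dose_map_kernel(tia, k, nuc)
        interior = (slice(4, 12),) * 3
        np.testing.assert_allclose(
            kern.values[interior], local.values[interior], rtol=0.01
        )

    def test_energy_conserved_for_interior_source(self):
        # all activity far enough from the grid edge: convolution must
        # conserve total deposited energy to within fft roundoff
        values = np.zeros((16, 16, 16))
        values[6:10, 6:10, 6:10] = 0.02
        tia = TIAMap(values, (4.0,) * 3, 0.0)
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.41)
        k = gaussian_kernel(sigma_vox=1.0, radius=3)
        local = dose_map_local(tia, nuc)
        kern = dose_map_kernel(tia, k, nuc)
        assert kern.values.sum() == pytest.approx(local.values.sum(), rel=1e-9)

    def test_invalid_kernels_rejected(self):
        tia = TIAMap(np.ones((4, 4, 4)), (4.0,) * 3, 0.0)
        nuc = NuclideSpec("test", 76.0, mean_energy_per_decay_MeV=1.0)
        with pytest.raises(ValueError, match="odd"):
            dose_map_kernel(tia, np.ones((2, 2, 2)), nuc)
        bad = np.ones((3, 3, 3))
        bad[0, 0, 0] = -0.1
        with pytest.raises(ValueError, match=">= 0"):
            dose_map_kernel(tia, bad, nuc)


class TestOrganDoseFromMap:
    def test_uniform_dose_for_every_organ(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[:3] = 1
        labels[3:, :3] = 2
        lm = LabelMap(labels, {1: "a", 2: "b"}, (4.0,) * 3)
        dose = DoseMap(np.full((6, 6, 6), 1.7), (4.0,) * 3, "local")
        organ = organ_dose_from_map(dose, lm)
        assert organ == {"a": pytest.approx(1.7), "b": pytest.approx(1.7)}

    def test_grid_mismatch_rejected(self):
        lm = LabelMap(np.ones((4, 4, 4), dtype=int), {1: "a"}, (4.0,) * 3)
        dose = DoseMap(np.ones((5, 5, 5)), (4.0,) * 3, "local")
        with pytest.raises(ValueError, match="grid"):
            organ_dose_from_map(dose, lm)

    def test_local_mode_organ_dose_closed_form(self, noiseless_study, nuclide, lam):
        # mean organ dose = (organ TIA / organ mass) x energy factor
        dyn = noiseless_study["dynamic"]
        labels = noiseless_study["labels"]
        injected = noiseless_study["injected_MBq"]
        tmap = voxel_tia_map(dyn, lam, injected)
        dose = dose_map_local(tmap, nuclide)
        organ = organ_dose_from_map(dose, labels)
        factor = 3.6e9 * nuclide.mean_energy_per_decay_MeV * 1.602e-13 * 1e6
        for organ_id, name in labels.legend.items():
            mass_kg = labels.organ_volume_mL(organ_id) / 1000.0
            expected = tmap.organ_tia(labels, organ_id) / mass_kg * factor
            assert organ[name] == pytest.approx(expected, rel=1e-6)
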
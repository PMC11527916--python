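"""DVH and plan-quality metrics against exhaustive voxel-count oracles."""

import numpy as np
import pytest

from doseret import (
    DoseGrid,
    compute_dvh,
    conformity_index,
    dose_at_volume,
    homogeneity_index,
    mean_max_dose,
    plan_metrics,
    volume_at_dose,
)
from doseret.dosimetry import metrics_table


@pytest.fixture()
def random_case(rng):
    dose = rng.random((16, 16, 16)) * 70.0
    mask = rng.random((16, 16, 16)) > 0.6
    return dose, mask


class TestDVH:
    def test_uniform_structure_step_curve(self):
        dose = np.full((8, 8, 8), 60.0)
        mask = np.ones_like(dose, dtype=bool)
        dvh = compute_dvh(dose, mask)
        assert dvh.volume_fraction_at(0.0) == 1.0
        assert dvh.volume_fraction_at(60.0) == 1.0
        assert dvh.volume_fraction_at(60.2) == 0.0

    def test_half_half_structure(self):
        dose = np.concatenate([np.full(50, 30.0), np.full(50, 10.0)]).reshape(10, 10, 1)
        mask = np.ones_like(dose, dtype=bool)
        dvh = compute_dvh(dose, mask)
        assert dvh.volume_fraction_at(20.0) == pytest.approx(0.5)

    def test_curve_equals_direct_counting_everywhere(self, random_case):
        dose, mask = random_case
        dvh = compute_dvh(dose, mask)
        voxels = dose[mask]
        for edge, frac in zip(dvh.bin_edges_gy, dvh.cum_volume_fraction):
            assert frac == pytest.approx((voxels >= edge).mean(), abs=1e-12)

    def test_monotone_nonincreasing(self, random_case):
        dose, mask = random_case
        dvh = compute_dvh(dose, mask)
        assert (np.diff(dvh.cum_volume_fraction) <= 0).all()

    def test_dmean_from_dvh_close_to_voxel_mean(self, random_case):
        dose, mask = random_case
        bw = 0.1
        dvh = compute_dvh(dose, mask, bin_width_gy=bw)
        # trapezoidal integral of the cumulative curve approximates the mean
        integral = np.trapezoid(dvh.cum_volume_fraction, dvh.bin_edges_gy)
        assert integral == pytest.approx(dose[mask].mean(), abs=bw)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))


class TestDoseAtVolume:
    def test_uniform_dose_all_percentiles_equal(self):
        dose = np.full((8, 8, 8), 60.0)
        mask = np.ones_like(dose, dtype=bool)
        for x in (2, 98, 99):
            assert dose_at_volume(dose, mask, x) == 60.0

    def test_hand_enumerated_rank(self):
        """100 voxels with doses 1..100 Gy: D2 is the 2nd-largest dose."""
        dose = np.arange(1.0, 101.0).reshape(10, 10, 1)
        mask = np.ones_like(dose, dtype=bool)
        assert dose_at_volume(dose, mask, 2) == 99.0
        assert dose_at_volume(dose, mask, 95) == 6.0
        assert dose_at_volume(dose, mask, 100) == 1.0

    def test_oracle_on_random_grids(self, rng):
        for _ in range(20):
            dose = rng.random((8, 8, 8)) * 70
            mask = rng.random((8, 8, 8)) > 0.5
            voxels = np.sort(dose[mask])[::-1]
            for x in (2.0, 50.0, 98.0):
                rank = int(np.ceil(x / 100 * voxels.size))
                assert dose_at_volume(dose, mask, x) == voxels[rank - 1]


class TestVolumeAtDose:
    def test_uniform_above_and_below(self):
        dose = np.full((4, 4, 4), 10.0)
        mask = np.ones_like(dose, dtype=bool)
        assert volume_at_dose(dose, mask, 5.0) == 100.0
        assert volume_at_dose(dose, mask, 20.0) == 0.0

    def test_strictly_greater_at_threshold(self):
        dose = np.full((4, 4, 4), 20.0)
        mask = np.ones_like(dose, dtype=bool)
        assert volume_at_dose(dose, mask, 20.0) == 0.0

    def test_counting_oracle(self, random_case):
        dose, mask = random_case
        for thr in (5.0, 20.0, 45.0):
            expected = 100.0 * (dose[mask] > thr).sum() / mask.sum()
            assert volume_at_dose(dose, mask, thr) == expected


class TestMeanMax:
    def test_two_voxel_case(self):
        dose = np.array([[[40.0, 50.0]]])
        mask = np.ones_like(dose, dtype=bool)
        assert mean_max_dose(dose, mask) == (45.0, 50.0)

    def test_matches_direct_computation(self, random_case):
        dose, mask = random_case
        dmean, dmax = mean_max_dose(dose, mask)
        assert dmean == pytest.approx(dose[mask].mean(), rel=1e-12)
        assert dmax == dose[mask].max()


class TestConformityIndex:
    def test_isodose_equals_ptv(self):
        dose = np.zeros((8, 8, 8))
        ptv = np.zeros((8, 8, 8), bool)
        ptv[2:5, 2:5, 2:5] = True
        dose[ptv] = 60.0
        ci, vtr, vt, vref = conformity_index(dose, ptv, 60.0)
        assert ci == 1.0 and vtr == vt == vref

    def test_full_coverage_double_isodose(self):
        """PTV covered, prescription isodose twice the PTV: CI = 1 x 0.5."""
        dose = np.zeros((8, 8, 8))
        ptv = np.zeros((8, 8, 8), bool)
        ptv[0:2, 0:4, 0:4] = True  # 32 voxels
        dose[0:4, 0:4, 0:4] = 60.0  # 64 voxels
        ci, vtr, vt, vref = conformity_index(dose, ptv, 60.0)
        assert (vtr, vt, vref) == (32, 32, 64)
        assert ci == pytest.approx(0.5)

    def test_nested_spheres_closed_form(self):
        """Spherical dose around a spherical PTV: CI from counted volumes."""
        n = 24
        g = np.ogrid[0:n, 0:n, 0:n]
        r2 = sum((a - (n - 1) / 2) ** 2 for a in g)
        ptv = r2 <= 5.0**2
        dose = np.where(r2 <= 7.0**2, 60.0, 20.0)
        ci, vtr, vt, vref = conformity_index(dose, ptv, 60.0)
        assert vtr == vt  # PTV fully inside the 60 Gy sphere
        assert ci == pytest.approx((vtr / vt) * (vtr / vref), rel=1e-12)

    def test_no_coverage_defined_zero_with_warning(self):
        dose = np.zeros((4, 4, 4))
        ptv = np.ones((4, 4, 4), bool)
        with pytest.warns(UserWarning):
            ci, *_ = conformity_index(dose, ptv, 60.0)
        assert ci == 0.0


class TestHomogeneityIndex:
    def test_printed_cohort_means_reproduce_two_decimal_values(self):
        """HI from published mean D2/D98 at 60 Gy prescription."""
        assert round(homogeneity_index(65.63, 58.69, 60.0), 2) == 0.12
        assert round(homogeneity_index(65.43, 57.67, 60.0), 2) == 0.13

    def test_homogeneous_dose_zero(self):
        assert homogeneity_index(60.0, 60.0, 60.0) == 0.0

    def test_linearity_mean_of_hi_is_hi_of_means(self, rng):
        d2 = 60 + rng.random(20) * 6
        d98 = 55 + rng.random(20) * 4
        his = [(a - b) / 60.0 for a, b in zip(d2, d98)]
        assert np.mean(his) == pytest.approx(
            homogeneity_index(d2.mean(), d98.mean(), 60.0), rel=1e-12
        )


class TestPlanMetrics:
    def test_fields_agree_with_standalone_operations(self, tiny_cohort):
        rec = tiny_cohort.records[0]
        m = plan_metrics(rec)
        dose, ss = rec.clinical_dose, rec.structures
        assert m.ptv_d2 == dose_at_volume(dose, ss["PTV"], 2)
        assert m.lung_v20 == volume_at_dose(dose, ss["total_lung"], 20)
        assert m.mld == mean_max_dose(dose, ss["total_lung"])[0]
        assert m.cord_dmax == mean_max_dose(dose, ss["spinal_cord"])[1]
        assert m.mhd == mean_max_dose(dose, ss["heart"])[0]
        assert m.ptv_hi == homogeneity_index(m.ptv_d2, m.ptv_d98, 60.0)

    def test_ordering_invariant_d2_d98_d99(self, tiny_cohort):
        for rec in tiny_cohort:
            m = plan_metrics(rec)
            assert m.ptv_d2 >= m.ptv_d98 >= m.ptv_d99
            assert 0 < m.ptv_ci <= 1

    def test_full_cohort_table_no_missing_values(self, tiny_cohort):
        table = metrics_table([plan_metrics(r) for r in tiny_cohort])
        assert len(table) == len(tiny_cohort)
        assert not table.isna().any().any()

    def test_virtual_dose_selection(self, tiny_cohort):
        m = plan_metrics(tiny_cohort.records[0], which_dose="virtual")
        assert m.ptv_d2 > 0
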
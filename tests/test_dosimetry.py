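import numpy as np
import pytest
from helpers import dvh_bruteforce, epl_dense_oracle, gamma_bruteforce, wilcoxon_enumeration

from mr2sct import dosimetry
from mr2sct.dosimetry import (
    BeamGeometry,
    DensityCalibration,
    GammaCriteria,
    compute_epl,
    dvh_metrics,
    enumerate_beam_angles,
    epl_sweep,
    gamma_2d,
    hu_to_red,
    paired_compare,
    simple_dose_2d,
    wilcoxon_signed_rank,
)
from mr2sct.errors import NoEntryError
from mr2sct.volume import BodyMask, DoseGrid, ImageVolume


def _cylinder(shape=(5, 61, 61), hu_inside=0.0, radius_frac=0.42, spacing=(2.5, 1.0, 1.0)):
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius_frac * shape[1]) ** 2
    hu = np.where(inside, hu_inside, -1000.0)
    return (
        ImageVolume(hu, spacing),
        BodyMask(inside, spacing),
        np.array([2 * spacing[0], cy * spacing[1], cx * spacing[2]]),
    )


class TestDensityCalibration:
    def test_anchor_values(self):
        assert hu_to_red(0.0) == 1.0
        assert hu_to_red(-1000.0) == 0.0

    def test_midpoint_interpolation(self):
        assert hu_to_red(500.0) == pytest.approx((1.0 + 1.52) / 2)

    def test_clipping_outside_anchor_range(self):
        assert hu_to_red(-2000.0) == 0.0
        assert hu_to_red(5000.0) == 2.5

    def test_unsorted_or_missing_anchor_rejected(self):
        with pytest.raises(ValueError):
            DensityCalibration(hu=[0.0, -1000.0], red=[1.0, 0.0])
        with pytest.raises(ValueError):
            DensityCalibration(hu=[-1000.0, 500.0], red=[0.0, 1.2])  # no water anchor


class TestEnumerateBeamAngles:
    def test_paper_arc_gives_180_unique_angles(self):
        angles = enumerate_beam_angles(181, 179, 2)
        assert len(angles) == 180
        assert len(set(angles)) == 180
        assert angles[0] == 181.0 and angles[-1] == 179.0
        assert 359.0 in angles and 1.0 in angles

    def test_single_angle(self):
        assert enumerate_beam_angles(0, 0, 2) == [0.0]

    def test_full_circle_at_two_degrees(self):
        assert len(enumerate_beam_angles(0, 358, 2)) == 180

    def test_nondividing_step_rejected(self):
        with pytest.raises(ValueError):
            enumerate_beam_angles(0, 179, 2)


class TestComputeEPL:
    def test_water_phantom_epl_equals_depth(self):
        ct, mask, iso = _cylinder(hu_inside=0.0)
        for ang in (0.0, 45.0, 90.0, 237.0):
            depth, epl = compute_epl(ct, mask, BeamGeometry(iso, ang))
            assert abs(epl - depth) <= 0.01

    def test_air_body_epl_zero(self):
        ct, mask, iso = _cylinder(hu_inside=-1000.0)
        depth, epl = compute_epl(ct, mask, BeamGeometry(iso, 30.0))
        assert depth > 0
        assert epl == pytest.approx(0.0, abs=1e-12)

    def test_layered_phantom_matches_dense_line_integral(self):
        """Half water / half RED-2 path, checked against a 2e5-sample oracle."""
        ct, mask, iso = _cylinder(hu_inside=0.0)
        hu_red2 = 1000.0 + (2.0 - 1.52) / (2.5 - 1.52) * 2000.0
        data = ct.data.copy()
        data[:, :18, :] = np.where(mask.data[:, :18, :], hu_red2, -1000.0)[...]
        ct2 = ImageVolume(data, ct.spacing)
        beam = BeamGeometry(iso, 0.0)  # ray travels toward -y, crossing the slab
        depth, epl = compute_epl(ct2, mask, beam)
        oracle = epl_dense_oracle(ct2, beam, depth)
        assert abs(epl - oracle) <= 0.05
        assert epl > depth  # denser-than-water slab lengthens the water-equivalent path

    def test_siddon_vs_dense_oracle_random_phantoms(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            ct, mask, iso = _cylinder(hu_inside=0.0)
            data = ct.data + rng.normal(0, 300, ct.shape) * mask.data
            ct2 = ImageVolume(np.clip(data, -1000, 2000), ct.spacing)
            ang = float(rng.uniform(0, 360))
            beam = BeamGeometry(iso, ang)
            depth, epl = compute_epl(ct2, mask, beam)
            assert abs(epl - epl_dense_oracle(ct2, beam, depth)) <= 0.05

    def test_epl_bounded_by_depth_times_max_red(self):
        rng = np.random.default_rng(1)
        ct, mask, iso = _cylinder(hu_inside=0.0)
        data = np.clip(ct.data + rng.normal(0, 500, ct.shape) * mask.data, -1000, 3000)
        ct2 = ImageVolume(data, ct.spacing)
        depth, epl = compute_epl(ct2, mask, BeamGeometry(iso, 123.0))
        assert epl <= depth * 2.5 + 1e-9

    def test_isocenter_outside_mask_rejected(self):
        ct, mask, _ = _cylinder()
        with pytest.raises(ValueError):
            compute_epl(ct, mask, BeamGeometry((2.5, 1.0, 1.0), 0.0))


class TestEPLSweep:
    def test_identical_volumes_zero_differences(self):
        ct, mask, iso = _cylinder()
        sweep = epl_sweep(ct, ct, mask, iso, enumerate_beam_angles(0, 350, 10))
        assert np.all(sweep.table["diff_mm"] == 0.0)
        assert sweep.frac_within_5mm == 1.0

    def test_paper_arc_emits_180_rows(self):
        ct, mask, iso = _cylinder(shape=(3, 41, 41))
        sweep = epl_sweep(ct, ct, mask, iso, enumerate_beam_angles(181, 179, 2))
        assert len(sweep.table) == 180

    def test_dense_ring_raises_epl_by_half_thickness(self):
        """Analytic slab oracle: a RED-1.5 annulus of thickness t adds 0.5*t."""
        shape = (3, 81, 81)
        ct_a, mask, iso = _cylinder(shape=shape, hu_inside=0.0, radius_frac=0.45)
        hu_red15 = (1.5 - 1.0) / 0.52 * 1000.0
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        t_mm = 6.0
        ring = (r >= 20.0) & (r < 20.0 + t_mm) & mask.data
        ct_b = ImageVolume(np.where(ring, hu_red15, ct_a.data), ct_a.spacing)
        sweep = epl_sweep(ct_a, ct_b, mask, iso, enumerate_beam_angles(0, 350, 10))
        expected = 0.5 * t_mm
        assert np.all(np.abs(sweep.table["diff_mm"] - expected) < 0.8)
        assert sweep.mean_diff == pytest.approx(expected, abs=0.4)


class TestGamma2D:
    def test_identical_distributions_gamma_zero(self):
        rng = np.random.default_rng(0)
        dose = 60.0 * rng.random((24, 24))
        for crit in dosimetry.STANDARD_CRITERIA:
            res = gamma_2d(dose, dose, (1.0, 1.0), crit, norm_dose=60.0)
            assert np.nanmax(res.gamma_map) == 0.0
            assert res.pass_rate == 100.0

    def test_uniform_two_percent_offset_is_boundary_pass(self):
        dose = np.full((20, 20), 50.0)
        ev = dose + 0.02 * 60.0
        res = gamma_2d(dose, ev, (1.0, 1.0), GammaCriteria(2, 2), norm_dose=60.0)
        assert np.allclose(res.gamma_map, 1.0, atol=1e-9)
        assert res.pass_rate == 100.0

    def test_reference_spike_of_six_percent_scores_two(self):
        dose = np.full((21, 21), 30.0)
        ref = dose.copy()
        ref[10, 10] += 0.06 * 60.0
        res = gamma_2d(ref, dose, (1.0, 1.0), GammaCriteria(3, 3), norm_dose=60.0)
        assert res.gamma_map[10, 10] == pytest.approx(2.0, abs=1e-9)

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(1)
        base = 40.0 + 10.0 * rng.random((16, 16))
        ev = base + rng.normal(0, 0.8, base.shape)
        for crit in (GammaCriteria(3, 3), GammaCriteria(2, 2)):
            res = gamma_2d(base, ev, (1.0, 1.0), crit, norm_dose=60.0)
            oracle = gamma_bruteforce(base, ev, (1.0, 1.0), crit.dose_percent, crit.dta_mm, 60.0)
            assert np.allclose(res.gamma_map, oracle, atol=1e-9)

    def test_pass_rate_monotone_across_criteria(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            ref = 40.0 + 15.0 * rng.random((24, 24))
            ev = ref + rng.normal(0, 1.0, ref.shape)
            rates = [
                gamma_2d(ref, ev, (1.0, 1.0), c, norm_dose=60.0).pass_rate
                for c in dosimetry.STANDARD_CRITERIA  # 3/3, 2/2, 1/1
            ]
            assert rates[0] >= rates[1] >= rates[2]

    def test_low_dose_cutoff_excludes_points(self):
        ref = np.linspace(0, 60, 100).reshape(10, 10)
        res = gamma_2d(ref, ref, (1.0, 1.0), GammaCriteria(3, 3), norm_dose=60.0,
                       low_dose_cutoff_frac=0.10)
        assert res.n_evaluated == int((ref >= 6.0).sum())
        assert np.isnan(res.gamma_map[ref < 6.0]).all()

    def test_zero_normalization_rejected(self):
        d = np.ones((4, 4))
        with pytest.raises(ValueError):
            gamma_2d(d, d, (1.0, 1.0), GammaCriteria(3, 3), norm_dose=0.0)


class TestDVH:
    def test_uniform_dose_degenerate_case(self):
        dose = DoseGrid(np.full((2, 5, 5), 57.0), (1, 1, 1), prescription=60.0)
        mask = BodyMask(np.ones(dose.shape, bool), (1, 1, 1))
        m = dvh_metrics(dose, mask)
        assert m.d2 == m.d50 == m.d98 == m.dmax == m.dmean == 57.0
        assert m.v95 == 100.0  # 57 >= 0.95 * 60
        low = dvh_metrics(DoseGrid(np.full((2, 5, 5), 56.0), (1, 1, 1), 60.0), mask)
        assert low.v95 == 0.0

    def test_linear_ramp_median(self):
        vals = np.linspace(0.0, 100.0, 101)
        dose = DoseGrid(vals.reshape(1, 1, -1), (1, 1, 1), prescription=100.0)
        mask = BodyMask(np.ones(dose.shape, bool), (1, 1, 1))
        m = dvh_metrics(dose, mask)
        assert m.d50 == pytest.approx(50.0, abs=1e-9)

    def test_matches_bruteforce_oracle_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            vals = rng.gamma(4.0, 12.0, size=(3, 9, 9))
            dose = DoseGrid(vals, (1, 1, 1), prescription=60.0)
            mask = BodyMask(rng.random(vals.shape) > 0.3, (1, 1, 1))
            m = dvh_metrics(dose, mask)
            oracle = dvh_bruteforce(vals[mask.data], 60.0)
            for key, got in m.to_dict().items():
                assert got == pytest.approx(oracle[key], abs=1e-9), key

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random((2, 6, 6)) * 70
        mask = BodyMask(np.ones(vals.shape, bool), (1, 1, 1))
        m1 = dvh_metrics(DoseGrid(vals, (1, 1, 1), 60.0), mask)
        shuffled = rng.permutation(vals.ravel()).reshape(vals.shape)
        m2 = dvh_metrics(DoseGrid(shuffled, (1, 1, 1), 60.0), mask)
        assert m1.to_dict() == pytest.approx(m2.to_dict())

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            vals = rng.random((1, 8, 8)) * 80
            m = dvh_metrics(DoseGrid(vals, (1, 1, 1), 60.0), BodyMask(np.ones(vals.shape, bool), (1, 1, 1)))
            assert m.d2 >= m.d50 >= m.d98
            assert m.dmax >= m.d2

    def test_empty_structure_rejected(self):
        dose = DoseGrid(np.ones((1, 3, 3)), (1, 1, 1), 60.0)
        with pytest.raises(ValueError):
            dvh_metrics(dose, BodyMask(np.zeros(dose.shape, bool), (1, 1, 1)))


class TestPairedCompare:
    def test_equal_samples_degenerate(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = paired_compare(a, a)
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_t_statistic_matches_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 20)
        b = a + rng.normal(0.5, 0.3, 20)
        res = paired_compare(a, b)
        d = b - a
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.test == "paired-t"
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)

    def test_wilcoxon_exact_small_sample(self):
        stat, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert p == pytest.approx(0.0625)
        assert p == pytest.approx(wilcoxon_enumeration([1, 2, 3, 4, 5]))

    def test_wilcoxon_matches_enumeration_on_mixed_signs(self):
        d = np.array([0.8, -1.6, 2.4, 3.1, -0.2, 1.1, 0.5])
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(wilcoxon_enumeration(d))

    def test_non_normal_differences_select_wilcoxon(self):
        rng = np.random.default_rng(3)
        a = np.zeros(30)
        b = rng.lognormal(0.0, 1.5, 30)  # heavily skewed differences
        res = paired_compare(a, b)
        assert res.test == "wilcoxon"
        assert 0.0 <= res.p_value <= 1.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0], [1.5, 2.5])


class TestSimpleDose2D:
    def test_isocenter_receives_prescription(self):
        ct = np.zeros((41, 41))
        dose = simple_dose_2d(ct, (1.0, 1.0), [0.0, 120.0, 240.0], prescription=20.0)
        assert dose[20, 20] == pytest.approx(20.0)

    def test_denser_ct_attenuates_beam_more(self):
        water = np.zeros((41, 41))
        bone = np.full((41, 41), 900.0)
        d_w = simple_dose_2d(water, (1.0, 1.0), [0.0], prescription=20.0)
        d_b = simple_dose_2d(bone, (1.0, 1.0), [0.0], prescription=20.0)
        # beyond the isocenter the denser medium keeps attenuating faster
        assert d_b[35, 20] / d_b[20, 20] < d_w[35, 20] / d_w[20, 20]
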
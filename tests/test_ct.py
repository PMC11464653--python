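"""CT densitometry: classification, quantification, banding, extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cralekit import ct
from cralekit import synthetic as syn


class TestClassifyHU:
    @pytest.mark.parametrize(
        "hu,label",
        [
            (-1000, "hyper"),
            (-950, "hyper"),
            (-901, "hyper"),
            (-900, "normal"),
            (-900.5, "normal"),  # sub-integer values fall at the midpoint split
            (-501, "normal"),
            (-500, "poor"),
            (-101, "poor"),
            (-100, "non"),
            (0, "non"),
            (100, "non"),
            (150, "out_of_range"),
            (-1001, "out_of_range"),
        ],
    )
    def test_compartment_boundaries(self, hu, label):
        assert ct.classify_hu(hu) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ct.classify_hu(float("nan"))

    def test_array_agrees_with_scalar(self):
        hu = np.linspace(-1100, 200, 501)
        codes = ct.classify_hu_array(hu)
        labels = [ct.classify_hu(v) for v in hu]
        lut = {-1: "out_of_range", 0: "hyper", 1: "normal", 2: "poor", 3: "non"}
        assert [lut[int(c)] for c in codes] == labels

    @given(st.floats(min_value=-1000, max_value=100))
    @settings(max_examples=200, derandomize=True)
    def test_in_range_always_classified(self, hu):
        assert ct.classify_hu(hu) in ct.COMPARTMENTS


class TestGasTissue:
    @pytest.mark.parametrize(
        "hu,gas,tissue",
        [(-1000, 1.0, 0.0), (0, 0.0, 1.0), (-500, 0.5, 0.5), (50, 0.0, 1.0)],
    )
    def test_decomposition(self, hu, gas, tissue):
        g, t = ct.voxel_gas_tissue(hu)
        assert g == pytest.approx(gas)
        assert t == pytest.approx(tissue)

    @given(st.floats(min_value=-1000, max_value=0))
    @settings(max_examples=100, derandomize=True)
    def test_conservation_below_water(self, hu):
        g, t = ct.voxel_gas_tissue(hu)
        assert g + t == pytest.approx(1.0, abs=1e-12)


class TestMeanLungDensity:
    def test_uniform(self, uniform_volume):
        vol, mask = uniform_volume(-400.0)
        assert ct.mean_lung_density(vol, mask) == pytest.approx(-400.0)

    def test_two_equal_slices(self):
        data = np.zeros((2, 4, 4))
        data[0], data[1] = -600.0, -200.0
        vol = ct.CTVolume(data=data, spacing_mm=(1, 1, 1))
        mask = ct.LungMask(data=np.ones_like(data, dtype=bool))
        assert ct.mean_lung_density(vol, mask) == pytest.approx(-400.0)

    def test_area_weighting_2_to_1(self):
        # slice areas 2:1 at -600/-300 -> (2*-600 + 1*-300)/3 = -500
        data = np.zeros((2, 1, 2))
        mask = np.zeros((2, 1, 2), dtype=bool)
        data[0, 0, :] = -600.0
        mask[0, 0, :] = True
        data[1, 0, 0] = -300.0
        mask[1, 0, 0] = True
        vol = ct.CTVolume(data=data, spacing_mm=(1, 1, 1))
        assert ct.mean_lung_density(vol, ct.LungMask(data=mask)) == pytest.approx(-500.0)

    def test_empty_mask_rejected(self, uniform_volume):
        vol, _ = uniform_volume(-400.0)
        with pytest.raises(ValueError):
            ct.LungMask(data=np.zeros(vol.data.shape, dtype=bool))


class TestQuantify:
    def test_uniform_arithmetic(self):
        # 100 000 voxels of 1 mm^3 at -500 HU: 100 mL, gas 50 mL, weight 50 g
        shape = (100, 100, 10)
        vol = ct.CTVolume(np.full(shape, -500.0), spacing_mm=(1, 1, 1))
        rep = ct.quantify(vol, ct.LungMask(np.ones(shape, dtype=bool)))
        assert rep.lung_volume_ml == pytest.approx(100.0)
        assert rep.gas_volume_ml == pytest.approx(50.0)
        assert rep.weight_g == pytest.approx(50.0)
        assert rep.f_poor == 1.0 and rep.crale

    def test_uniform_hyper(self, uniform_volume):
        vol, mask = uniform_volume(-950.0)
        rep = ct.quantify(vol, mask)
        assert rep.f_hyper == 1.0
        assert rep.f_normal == rep.f_poor == rep.f_non == 0.0

    def test_matches_phantom_truth(self, small_phantom):
        vol, mask, truth = small_phantom
        rep = ct.quantify(vol, mask)
        assert rep.gas_volume_ml == pytest.approx(truth.gas_volume_ml, rel=1e-3)
        assert rep.weight_g == pytest.approx(truth.weight_g, rel=1e-3)
        assert rep.mean_density_hu == pytest.approx(truth.mean_density_hu, abs=0.5)

    def test_shape_mismatch_rejected(self, uniform_volume):
        vol, _ = uniform_volume(-400.0)
        bad = ct.LungMask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError):
            ct.quantify(vol, bad)

    def test_partition_of_unity_and_conservation(self, small_phantom):
        vol, mask, _ = small_phantom
        rep = ct.quantify(vol, mask)
        assert rep.f_hyper + rep.f_normal + rep.f_poor + rep.f_non == pytest.approx(1.0)
        assert rep.gas_volume_ml + rep.weight_g == pytest.approx(
            rep.lung_volume_ml, rel=5e-3
        )

    def test_axis_permutation_invariance(self, small_phantom):
        vol, mask, _ = small_phantom
        ref = ct.quantify(vol, mask)
        perm = (1, 2, 0)
        vol_p = ct.CTVolume(
            data=np.transpose(vol.data, perm),
            spacing_mm=tuple(vol.spacing_mm[i] for i in perm),
            axis_roles=tuple(vol.axis_roles[i] for i in perm),
        )
        mask_p = ct.LungMask(np.transpose(mask.data, perm))
        got = ct.quantify(vol_p, mask_p)
        assert got.gas_volume_ml == pytest.approx(ref.gas_volume_ml, rel=1e-12)
        assert got.weight_g == pytest.approx(ref.weight_g, rel=1e-12)
        assert got.mean_density_hu == pytest.approx(ref.mean_density_hu, rel=1e-12)

    def test_oracle_equivalence_naive_loop(self):
        """quantify matches an independent per-voxel Python loop."""
        rng = np.random.default_rng(0)
        shape = (12, 10, 8)
        data = rng.uniform(-1100, 150, size=shape)  # includes out-of-range
        mask = rng.random(shape) > 0.4
        vol = ct.CTVolume(data, spacing_mm=(1.5, 1.0, 2.0))
        rep = ct.quantify(vol, ct.LungMask(mask))

        vv = 1.5 * 1.0 * 2.0 / 1000.0
        gas = weight = n = hu_sum = 0.0
        counts = {c: 0 for c in ct.COMPARTMENTS}
        n_out = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if not mask[i, j, k]:
                        continue
                    hu = data[i, j, k]
                    n += 1
                    hu_sum += hu
                    gas += -min(max(hu, -1000.0), 0.0) / 1000.0 * vv
                    weight += min(1.0 + min(max(hu, -1000.0), 100.0) / 1000.0, 1.0) * vv
                    label = ct.classify_hu(hu)
                    if label == "out_of_range":
                        n_out += 1
                    else:
                        counts[label] += 1
        assert rep.gas_volume_ml == pytest.approx(gas, rel=1e-9)
        assert rep.weight_g == pytest.approx(weight, rel=1e-9)
        assert rep.mean_density_hu == pytest.approx(hu_sum / n, rel=1e-9)
        assert rep.n_out_of_range == n_out
        in_range = n - n_out
        for c in ct.COMPARTMENTS:
            assert rep.fractions[c] == pytest.approx(counts[c] / in_range, abs=1e-12)

    def test_edema_shift_monotonicity(self, small_phantom_params):
        from dataclasses import replace

        weights, nonpoor, means = [], [], []
        for shift in (0.0, 100.0, 225.0):
            vol, mask, _ = syn.gen_ct_phantom(
                replace(small_phantom_params, edema_shift_hu=shift)
            )
            rep = ct.quantify(vol, mask)
            weights.append(rep.weight_g)
            nonpoor.append(rep.f_poor + rep.f_non)
            means.append(rep.mean_density_hu)
        assert weights == sorted(weights) and weights[0] < weights[-1]
        assert nonpoor == sorted(nonpoor) and nonpoor[0] < nonpoor[-1]
        assert means == sorted(means)


class TestGravitationalProfile:
    def test_flat_phantom_equal_bands(self, small_phantom_params):
        from dataclasses import replace

        vol, mask, _ = syn.gen_ct_phantom(
            replace(small_phantom_params, vd_slope_hu=0.0)
        )
        prof = ct.gravitational_profile(vol, mask)
        means = [b.mean_hu for b in prof.bands]
        assert max(means) - min(means) < 1e-9

    def test_band_counts_partition_mask(self, small_phantom):
        vol, mask, _ = small_phantom
        prof = ct.gravitational_profile(vol, mask)
        assert sum(b.n_voxels for b in prof.bands) == int(mask.data.sum())

    def test_linear_field_box_mask_exact_band_means(self):
        """On a box mask the three bands are exact row thirds, so band
        means of a row-linear field equal the hand-computed row averages."""
        shape = (4, 30, 6)
        row_hu = np.linspace(-700, -200, shape[1])
        data = np.broadcast_to(row_hu[None, :, None], shape).copy()
        vol = ct.CTVolume(data, spacing_mm=(1, 1, 1))
        prof = ct.gravitational_profile(vol, ct.LungMask(np.ones(shape, dtype=bool)))
        expected = [row_hu[:10].mean(), row_hu[10:20].mean(), row_hu[20:].mean()]
        got = [b.mean_hu for b in prof.bands]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_linear_slope_cylinder_matches_analytic(self):
        """Band means of a linear depth field over an elliptic cylinder
        match the continuous integral weighted by the elliptical chord
        length sqrt(d(1-d)) to within discretisation (< 0.5 HU)."""
        shape = (4, 280, 240)
        rr = (np.arange(shape[1]) - (shape[1] - 1) / 2) / 130.0
        cc_ = (np.arange(shape[2]) - (shape[2] - 1) / 2) / 110.0
        ell = (rr[:, None] ** 2 + cc_[None, :] ** 2) <= 1.0
        mask = np.broadcast_to(ell[None], shape).copy()
        rows = np.where(ell.any(axis=1))[0]
        lo, hi = rows[0], rows[-1]
        depth = np.clip((np.arange(shape[1]) - lo) / (hi - lo), 0, 1)
        base, slope = -500.0, 200.0
        field = base + slope * (depth - 0.5)
        data = np.broadcast_to(field[None, :, None], shape).copy()
        vol = ct.CTVolume(data, spacing_mm=(3.0, 0.5, 0.5))
        prof = ct.gravitational_profile(vol, ct.LungMask(mask))

        from scipy.integrate import quad

        # normalized depth spans the discrete row range, which stops half
        # a voxel short of the continuous ellipse edge: rescale the chord
        rho = (hi - (shape[1] - 1) / 2) / 130.0
        chord = lambda d: np.sqrt(max(1.0 - ((2 * d - 1) * rho) ** 2, 0.0))

        def band_mean(a, b):
            f = lambda d: (base + slope * (d - 0.5)) * chord(d)
            return quad(f, a, b)[0] / quad(chord, a, b)[0]

        expected = [band_mean(0, 1 / 3), band_mean(1 / 3, 2 / 3), band_mean(2 / 3, 1)]
        got = [b.mean_hu for b in prof.bands]
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=0.5)
        assert got[0] < got[1] < got[2]

    def test_dorsal_band_denser_with_positive_slope(self, small_phantom):
        vol, mask, _ = small_phantom
        prof = ct.gravitational_profile(vol, mask)
        assert prof.bands[-1].mean_hu > prof.bands[0].mean_hu


class TestVentrodorsalGradient:
    @pytest.mark.parametrize(
        "ventral,dorsal,expected",
        [(-600, -600, 0.0), (-600, -300, 50.0), (-800, -200, 75.0)],
    )
    def test_arithmetic(self, ventral, dorsal, expected):
        prof = ct.GravitationalProfile(
            bands=(
                ct.BandStats("ventral", ventral, 1, {}),
                ct.BandStats("mid", (ventral + dorsal) / 2, 1, {}),
                ct.BandStats("dorsal", dorsal, 1, {}),
            ),
            boundary_definition="test",
        )
        assert ct.ventrodorsal_gradient(prof) == pytest.approx(expected)

    def test_zero_ventral_rejected(self):
        prof = ct.GravitationalProfile(
            bands=(
                ct.BandStats("ventral", 0.0, 1, {}),
                ct.BandStats("dorsal", -100.0, 1, {}),
            ),
            boundary_definition="test",
        )
        with pytest.raises(ValueError):
            ct.ventrodorsal_gradient(prof)


class TestSelectSlices:
    def _mask_spanning(self, first, last, n_slices=100):
        m = np.zeros((n_slices, 4, 4), dtype=bool)
        m[first : last + 1] = True
        return ct.LungMask(m)

    def test_even_spacing_0_to_90(self):
        assert ct.select_slices(self._mask_spanning(0, 90), 0) == list(range(0, 91, 10))

    def test_span_exactly_ten(self):
        assert ct.select_slices(self._mask_spanning(5, 14), 0) == list(range(5, 15))

    def test_identity_on_0_to_9(self):
        assert ct.select_slices(self._mask_spanning(0, 9, 10), 0) == list(range(10))

    def test_narrow_span_rejected(self):
        with pytest.raises(ValueError):
            ct.select_slices(self._mask_spanning(0, 5), 0, n=10)

    def test_collisions_respread_unique(self):
        idx = ct.select_slices(self._mask_spanning(0, 12), 0)
        assert len(idx) == 10 and len(set(idx)) == 10
        assert idx[0] == 0 and idx[-1] == 12


class TestExtrapolation:
    def test_constant_profile_equals_full_volume(self, uniform_volume):
        vol, mask = uniform_volume(-500.0, shape=(30, 8, 8))
        full = ct.quantify(vol, mask)
        est = ct.ten_slice_report(vol, mask)
        assert est.gas_volume_ml == pytest.approx(full.gas_volume_ml, rel=1e-9)
        assert est.weight_g == pytest.approx(full.weight_g, rel=1e-9)
        assert est.lung_volume_ml == pytest.approx(full.lung_volume_ml, rel=1e-9)

    def test_linear_profile_exact(self):
        # per-slice gas varies linearly cranio-caudally on a box mask:
        # trapezoid over linearly interpolated samples is exact
        shape = (40, 10, 10)
        hu = np.linspace(-800, -300, shape[0])[:, None, None]
        vol = ct.CTVolume(np.broadcast_to(hu, shape).copy(), spacing_mm=(2, 1, 1))
        mask = ct.LungMask(np.ones(shape, dtype=bool))
        full = ct.quantify(vol, mask)
        est = ct.ten_slice_report(vol, mask)
        assert est.gas_volume_ml == pytest.approx(full.gas_volume_ml, rel=5e-3)
        assert est.weight_g == pytest.approx(full.weight_g, rel=5e-3)

    def test_smooth_phantom_within_3pct(self, small_phantom):
        vol, mask, _ = small_phantom
        full = ct.quantify(vol, mask)
        est = ct.ten_slice_report(vol, mask)
        assert est.gas_volume_ml == pytest.approx(full.gas_volume_ml, rel=0.03)
        assert est.weight_g == pytest.approx(full.weight_g, rel=0.03)

    def test_bad_positions_rejected(self):
        rep = ct.AerationReport(1, 0.5, 0.5, -500, 0, 0, 1, 0, True, 100)
        with pytest.raises(ValueError):
            ct.extrapolate_whole_lung([rep, rep], [5.0, 2.0], 1.0, (0.0, 10.0))
        with pytest.raises(ValueError):
            ct.extrapolate_whole_lung([rep, rep], [2.0, 50.0], 1.0, (0.0, 10.0))
        with pytest.raises(ValueError):
            ct.extrapolate_whole_lung([rep], [2.0], 1.0, (0.0, 10.0))


class TestDetectCrale:
    @pytest.mark.parametrize(
        "mean,flag",
        [(-324.0, True), (-500.0, True), (-499.9, True), (-501.0, False), (-549.0, False)],
    )
    def test_threshold_inclusive(self, mean, flag):
        assert ct.detect_crale(mean) is flag
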
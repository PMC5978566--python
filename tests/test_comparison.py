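import numpy as np
import pytest
from PIL import Image

import episense as ep
from episense import Category, ComparisonCriteria, ComparisonResult
from conftest import PITCH, render
from oracles import bump_field, dta_brute_force, gamma_brute_force


def crit(**kw):
    return ComparisonCriteria(**kw)


class TestCriteriaValidation:
    def test_gamma_needs_both_tolerances(self):
        with pytest.raises(ValueError, match="dd_only"):
            crit(dd_tol_percent=0.0, dta_tol_mm=2.0, mode="gamma")

    def test_threshold_range(self):
        with pytest.raises(ValueError):
            crit(threshold_percent=100.0)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            crit(mode="dd_and_dta")


class TestIdentity:
    @pytest.mark.parametrize("mode", ["dd_only", "dta_only", "gamma"])
    def test_all_modes_null_on_identical_images(self, open_field_10, mode):
        c = crit(dd_tol_percent=1.0, dta_tol_mm=1.0, mode=mode)
        res = ep.compare(open_field_10, open_field_10, c)
        evaluated = res.category_map != Category.EXCLUDED
        assert np.all(res.metric_map[evaluated] == 0)
        assert res.passing_rate == 100.0


class TestDoseDifference:
    def test_uniform_scaling_all_hot(self, uniform_pair):
        ref, ev = uniform_pair
        res = ep.dd_map(ev, ref, crit(dd_tol_percent=0.4, mode="dd_only"))
        evaluated = res.category_map != Category.EXCLUDED
        assert np.allclose(res.metric_map[evaluated], 0.5)
        assert np.all(res.category_map[evaluated] == Category.FAIL_HOT)

    def test_equality_passes_at_boundary(self, uniform_pair):
        ref, ev = uniform_pair
        res = ep.dd_map(ev, ref, crit(dd_tol_percent=0.5, mode="dd_only"))
        assert res.passing_rate == 100.0

    def test_antisymmetric_under_swap(self, jaw_shift_pair):
        ref, ev = jaw_shift_pair
        c = crit(dd_tol_percent=1.0, mode="dd_only")
        fwd = ep.dd_map(ev, ref, c)
        # Swapping roles also swaps the normalization image; on this pair
        # both maxima coincide, so the maps are exact negatives.
        rev = ep.dd_map(ref, ev, c)
        evaluated = (fwd.category_map != Category.EXCLUDED) & (
            rev.category_map != Category.EXCLUDED
        )
        assert np.allclose(fwd.metric_map[evaluated], -rev.metric_map[evaluated])

    def test_threshold_excludes_low_dose_and_rate_unchanged(self, open_field_10):
        ref = open_field_10
        ev = ref.copy()
        res0 = ep.dd_map(ev, ref, crit(dd_tol_percent=0.5, mode="dd_only"))
        # Corrupt only pixels below the 10% threshold: the passing rate
        # must not move.
        below = ref.values < 0.10 * ref.values.max()
        ev.values[below] += 5.0
        res1 = ep.dd_map(ev, ref, crit(dd_tol_percent=0.5, mode="dd_only"))
        assert res1.passing_rate == res0.passing_rate
        assert np.all(res1.category_map[below] == Category.EXCLUDED)

    def test_grid_mismatch_rejected(self, open_field_10):
        other = ep.DoseImage(np.ones((10, 10)), PITCH, 1500.0)
        with pytest.raises(ValueError, match="grid"):
            ep.dd_map(other, open_field_10, crit(mode="dd_only"))

    def test_zero_baseline_rejected(self):
        zero = ep.DoseImage(np.zeros((8, 8)), PITCH, 1500.0)
        with pytest.raises(ValueError, match="normalization"):
            ep.dd_map(zero, zero, crit(mode="dd_only"))


class TestDistanceToAgreement:
    def test_translated_edge_fails_below_and_passes_at_shift(self, jaw_shift_pair):
        ref, ev = jaw_shift_pair
        tight = ep.dta_map(ev, ref, crit(dta_tol_mm=1.4, mode="dta_only"))
        loose = ep.dta_map(ev, ref, crit(dta_tol_mm=1.5, mode="dta_only"))
        assert np.any(tight.category_map == Category.FAIL_GEOMETRIC)
        assert not np.any(loose.category_map == Category.FAIL_GEOMETRIC)

    def test_edge_dta_equals_translation(self, jaw_shift_pair):
        ref, ev = jaw_shift_pair
        res = ep.dta_map(ev, ref, crit(dta_tol_mm=2.0, mode="dta_only"))
        finite = np.isfinite(res.metric_map) & (res.metric_map > 0)
        assert res.metric_map[finite].max() == pytest.approx(1.5, abs=0.1)

    def test_invariant_under_common_translation(self):
        # Moving both field edges identically leaves the DTA map unchanged
        # up to sub-pixel sampling effects.
        base = ep.open_field(10.0, 10.0)
        shifted = ep.BeamConfig(jaws_mm=(42.1875, 57.8125, 50.0, 50.0))  # 10 px shift
        pairs = []
        for nominal in (base, shifted):
            err, _ = ep.inject_error(nominal, None, "jaw_shift", jaw="Y1", shift_mm=1.0)
            res = ep.dta_map(
                render(err), render(nominal), crit(dta_tol_mm=2.0, mode="dta_only")
            )
            m = res.metric_map
            pairs.append(m[np.isfinite(m)].max())
        assert pairs[0] == pytest.approx(pairs[1], abs=0.02)

    def test_brute_force_oracle_single_seed(self):
        ref = bump_field(21)
        ev = bump_field(21, shift_mm=(2.0, 0.0))
        res = ep.dta_map(ev, ref, crit(dta_tol_mm=2.0, mode="dta_only", search_radius_mm=6.0))
        oracle = dta_brute_force(ev, ref)
        m = res.category_map != Category.EXCLUDED
        a, b = res.metric_map[m], oracle[m]
        assert np.array_equal(np.isfinite(a), np.isfinite(b))
        both = np.isfinite(a)
        assert np.abs(a[both] - b[both]).max() < 0.05


class TestGamma:
    def test_uniform_offset_on_plateau_is_boundary_pass(self, open_field_10):
        ref = open_field_10
        c = crit(dd_tol_percent=2.0, dta_tol_mm=2.0, mode="gamma")
        bump = 2.0 / 100.0 * ref.values.max()
        ev = ep.DoseImage(ref.values + bump, ref.pixel_pitch_mm, ref.plane_sdd_mm, ref.origin)
        res = ep.gamma_map(ev, ref, c)
        center = res.metric_map[192, 256]
        assert center == pytest.approx(1.0, abs=1e-6)
        assert res.category_map[192, 256] == Category.PASS

    def test_gamma_bounded_by_single_criterion_metrics(self, jaw_shift_pair):
        # gamma minimises over a superset of each single-criterion search:
        # at the same pixel it can never exceed |DD| normalized by the dose
        # tolerance, and it can exceed DTA normalized by the distance
        # tolerance only by the gamma lattice's own resolution (half a
        # step of position, plus the dose picked up over that half step).
        ref, ev = jaw_shift_pair
        dd_tol, dta_tol = 2.0, 1.0
        c = crit(dd_tol_percent=dd_tol, dta_tol_mm=dta_tol, mode="gamma")
        g = ep.gamma_map(ev, ref, c)
        dd = ep.dd_map(ev, ref, crit(dd_tol_percent=dd_tol, mode="dd_only"))
        dta = ep.dta_map(ev, ref, crit(dta_tol_mm=dta_tol, mode="dta_only"))
        m = g.category_map != Category.EXCLUDED
        assert np.all(g.metric_map[m] <= np.abs(dd.metric_map[m]) / dd_tol + 1e-9)
        # Distance side: at the DTA agreement point the doses match within
        # the baseline's interpolation-error tolerance, and the gamma
        # lattice reaches within half a step of that point, picking up at
        # most the local gradient times that half step in dose.
        from scipy import ndimage
        from oracles import node_match_tolerance

        norm = ref.values.max()
        pitch = ref.pixel_pitch_mm
        radius_px = 2 * int(np.ceil(c.radius_mm / pitch)) + 1
        ntol = ndimage.maximum_filter(
            node_match_tolerance(ref.values, 2.0 ** -16 * norm), radius_px, mode="nearest"
        )
        gy, gx = np.gradient(ref.values, pitch)
        grad = ndimage.maximum_filter(np.hypot(gy, gx), radius_px, mode="nearest")
        half_step = c.step_mm / 2.0
        dd_abs = dd_tol / 100.0 * norm
        bound = np.sqrt(
            ((dta.metric_map + half_step) / dta_tol) ** 2
            + ((ntol + grad * half_step) / dd_abs) ** 2
        )
        assert np.all(g.metric_map[m] <= bound[m] + 1e-6)

    def test_monotone_in_criteria(self, jaw_shift_pair):
        ref, ev = jaw_shift_pair
        rates = [
            ep.gamma_map(ev, ref, crit(dd_tol_percent=t, dta_tol_mm=t, mode="gamma")).passing_rate
            for t in (0.5, 1.0, 2.0)
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_brute_force_oracle_single_seed(self):
        ref = bump_field(31, n=24)
        ev = bump_field(32, n=24)
        c = crit(
            dd_tol_percent=2.0,
            dta_tol_mm=2.0,
            mode="gamma",
            refine_step_mm=0.025,
            search_radius_mm=4.0,
        )
        res = ep.gamma_map(ev, ref, c)
        oracle = gamma_brute_force(ev, ref, 2.0, 2.0)
        m = res.category_map != Category.EXCLUDED
        assert np.abs(res.metric_map - oracle)[m].max() < 0.02


class TestPassingRateAndRendering:
    def test_rate_arithmetic(self):
        cat = np.full((10, 10), Category.PASS, dtype=np.int8)
        cat[0, :5] = Category.FAIL_HOT
        res = ComparisonResult(np.zeros((10, 10)), cat, crit(mode="dd_only"), 100.0, 0.6, 0.0)
        assert res.passing_rate == pytest.approx(95.0)

    def test_all_excluded_is_undefined(self):
        cat = np.full((4, 4), Category.EXCLUDED, dtype=np.int8)
        res = ComparisonResult(np.zeros((4, 4)), cat, crit(mode="dd_only"), 100.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            ep.passing_rate(res)

    def test_category_map_png_palette(self, tmp_path):
        cat = np.array(
            [
                [Category.PASS, Category.FAIL_HOT],
                [Category.FAIL_COLD, Category.FAIL_GEOMETRIC],
            ],
            dtype=np.int8,
        )
        res = ComparisonResult(np.zeros((2, 2)), cat, crit(mode="dd_only"), 100.0, 0.0, 0.0)
        path = tmp_path / "map.png"
        ep.render_category_map(res, str(path))
        rgb = np.asarray(Image.open(path))
        assert tuple(rgb[0, 0]) == (0, 160, 0)  # pass: green
        assert tuple(rgb[0, 1]) == (220, 0, 0)  # hot: red
        assert tuple(rgb[1, 0]) == (0, 0, 220)  # cold: blue
        assert tuple(rgb[1, 1]) == (255, 140, 0)  # geometric: orange
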
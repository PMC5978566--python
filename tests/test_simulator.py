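import math

import numpy as np
import pytest

import episense as ep
from episense import (
    BeamConfig,
    ConfigurationError,
    CouchTop,
    NoiseModel,
    PhantomScene,
    PlaneGeometry,
    SlabPhantom,
    inject_error,
    make_head_phantom,
    millennium120,
    open_field,
    project_aperture,
    render_image,
)
from conftest import PANEL, PITCH, render


class TestApertureProjection:
    def test_magnification_of_jaw_edge(self):
        # A jaw edge 50 mm off-axis at isocenter projects to 75 mm on a
        # detector mounted at 1.5x magnification.
        polys = project_aperture(open_field(10.0, 10.0))
        xs = np.concatenate([p[:, 0] for p in polys])
        assert xs.max() == pytest.approx(75.0)
        assert xs.min() == pytest.approx(-75.0)

    def test_one_mm_jaw_shift_is_1p5_mm_on_detector(self):
        beam, _ = inject_error(open_field(10.0, 10.0), None, "jaw_shift", jaw="X2", shift_mm=1.0)
        polys = project_aperture(beam)
        xs = np.concatenate([p[:, 0] for p in polys])
        assert xs.max() == pytest.approx(76.5)
        assert xs.min() == pytest.approx(-75.0)  # only the shifted edge moves

    def test_collimator_rotation_edge_deviation(self):
        # 1 degree on the 15 cm detector-plane square: the edge endpoints
        # deviate from the nominal edge line by 1.3 mm (one decimal).
        beam, _ = inject_error(
            open_field(10.0, 10.0), None, "collimator_rotation", angle_deg=1.0
        )
        (corners,) = project_aperture(beam)
        max_dev = max(
            max(abs(abs(x) - 75.0) for x in corners[:, 0]),
            max(abs(abs(y) - 75.0) for y in corners[:, 1]),
        )
        assert round(max_dev, 1) == 1.3

    def test_mlc_intersected_with_jaws(self):
        mlc = millennium120(left_mm=-80.0, right_mm=80.0)
        beam = BeamConfig(jaws_mm=(50.0, 50.0, 50.0, 50.0), mlc=mlc)
        polys = project_aperture(beam)
        xs = np.concatenate([p[:, 0] for p in polys])
        ys = np.concatenate([p[:, 1] for p in polys])
        assert xs.max() <= 75.0 + 1e-9 and ys.max() <= 75.0 + 1e-9


class TestRenderPhysics:
    def test_flat_open_field(self, open_field_10):
        img = open_field_10
        y, x = img.coords_mm()
        plateau = img.values[np.ix_(np.abs(y) < 60, np.abs(x) < 60)]
        assert img.values[PANEL[0] // 2, PANEL[1] // 2] == pytest.approx(100.0)
        assert plateau.max() - plateau.min() < 1e-9

    def test_dose_linear_in_mu_and_output(self, open_field_10):
        img2 = render(BeamConfig(mu=250.0, output_scale=1.005))
        ratio = 2.5 * 1.005
        mask = open_field_10.values > 1e-6
        assert np.allclose(img2.values[mask] / open_field_10.values[mask], ratio, rtol=1e-12)

    def test_slab_attenuation_closed_form(self, open_field_10):
        scene = PhantomScene(slab=SlabPhantom(thickness_cm=20.0, mu_eff_per_cm=0.0475))
        img = render(open_field(10.0, 10.0), scene)
        center = img.values[PANEL[0] // 2, PANEL[1] // 2]
        assert center / 100.0 == pytest.approx(math.exp(-0.95), rel=1e-12)

    def test_penumbra_50_percent_level_on_projected_edge(self):
        # The erf edge profile puts the half-dose point exactly on the
        # geometric edge, independent of the penumbra width.
        img = render_image(
            open_field(1.0, 1.0), pitch_mm=0.1, panel_shape=(40, 400)
        )
        row = img.values[20]
        _, x = img.coords_mm()
        half = row.max() / 2.0
        idx = np.nonzero((row[:-1] >= half) & (row[1:] < half))[0][-1]
        frac = (row[idx] - half) / (row[idx] - row[idx + 1])
        crossing = x[idx] + frac * (x[idx + 1] - x[idx])
        assert abs(crossing - 7.5) < 0.01

    def test_penumbra_antisymmetry_about_edge(self):
        img = render_image(open_field(1.0, 1.0), pitch_mm=0.1, panel_shape=(40, 400))
        row = img.values[20]
        _, x = img.coords_mm()
        plateau = row.max()
        for d in (0.5, 1.0, 2.0):
            up = np.interp(7.5 - d, x, row)
            down = np.interp(7.5 + d, x, row)
            assert up + down == pytest.approx(plateau, abs=1e-6 * plateau)

    def test_empty_aperture_warns_and_zeroes(self):
        mlc = millennium120(left_mm=0.0, right_mm=0.0)
        mlc.left_positions_mm[55] = 140.0
        mlc.right_positions_mm[55] = 160.0
        beam = BeamConfig(jaws_mm=(200.0, 200.0, 200.0, 200.0), mlc=mlc)
        with pytest.warns(UserWarning, match="outside the panel"):
            img = render_image(beam, pitch_mm=0.78125, panel_shape=(64, 64))
        assert np.all(img.values == 0)

    def test_noise_determinism_and_seed_sensitivity(self):
        a = render(open_field(10.0, 10.0), noise=NoiseModel(0.002, seed=7))
        b = render(open_field(10.0, 10.0), noise=NoiseModel(0.002, seed=7))
        c = render(open_field(10.0, 10.0), noise=NoiseModel(0.002, seed=8))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_couch_strip_pattern_periodicity(self):
        # Shifting the strip pattern by one full pitch reproduces the image
        # away from the panel border.
        scene = PhantomScene(couch=CouchTop())
        a = render(open_field(10.0, 10.0), scene)
        _, moved = inject_error(open_field(10.0, 10.0), scene, "couch_shift", lateral_mm=30.0)
        b = render(open_field(10.0, 10.0), moved)
        interior = np.s_[60:-60, 80:-80]
        assert np.allclose(a.values[interior], b.values[interior], atol=1e-9)


class TestErrorInjection:
    def test_nominal_objects_untouched(self):
        beam = open_field(10.0, 10.0)
        scene = PhantomScene(couch=CouchTop())
        inject_error(beam, scene, "jaw_shift", jaw="X1", shift_mm=2.0)
        inject_error(beam, scene, "couch_shift", lateral_mm=2.0)
        assert beam.jaws_mm == (50.0, 50.0, 50.0, 50.0)
        assert scene.couch.lateral_offset_mm == 0.0

    def test_zero_magnitude_is_bit_identical(self):
        nominal = ep.mlc_shaped_field()
        beam, _ = inject_error(nominal, None, "mlc_shift", leaves=[25], bank="left", shift_mm=0.0)
        a = render(nominal)
        b = render(beam)
        assert np.array_equal(a.values, b.values)

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ConfigurationError, match="jaw_shift"):
            inject_error(open_field(10.0, 10.0), None, "gantry_sag")

    def test_mlc_pattern_only_listed_leaves_move(self):
        nominal = ep.mlc_shaped_field()
        beam, _ = inject_error(
            nominal, None, "mlc_shift", leaves=[25, 29], bank="left", shift_mm=[1.0, 2.0]
        )
        delta = nominal.mlc.left_positions_mm - beam.mlc.left_positions_mm
        assert delta[25] == pytest.approx(1.0)
        assert delta[29] == pytest.approx(2.0)
        untouched = np.delete(np.arange(60), [25, 29])
        assert np.all(delta[untouched] == 0)
        assert np.array_equal(nominal.mlc.right_positions_mm, beam.mlc.right_positions_mm)


class TestHeadPhantom:
    def test_reproducible_given_seed(self):
        a = make_head_phantom(11)
        b = make_head_phantom(11)
        assert np.array_equal(a.attenuation_map, b.attenuation_map)

    def test_zero_path_only_outside_contour(self):
        head = make_head_phantom(5)
        vals = head.attenuation_map
        assert np.any(vals == 0.0)  # air outside the head
        inside = vals > 0
        assert vals[inside].min() >= 0.35  # tissue floor, no near-zero limbo

    def test_contains_bone_and_air_structures(self):
        head = make_head_phantom(5)
        vals = head.attenuation_map
        inside = vals > 0
        # Bone-like excess above the plain ellipsoid chord and cavity
        # deficits below it must both be present.
        assert vals.max() > 18.0
        assert np.percentile(vals[inside], 5) < 8.0

    def test_pose_identity_at_zero(self):
        head = make_head_phantom(2)
        x = np.linspace(-40, 40, 33)
        y = np.linspace(-50, 50, 33)
        xx, yy = np.meshgrid(x, y)
        assert np.allclose(head.path_length_cm(xx, yy), head.copy().path_length_cm(xx, yy))

    def test_roll_severity_strictly_ordered(self):
        # A 1 degree roll must degrade the gamma passing rate strictly more
        # than a 0.5 degree roll of the same phantom.
        beam = open_field(9.0, 11.5)
        scene = PhantomScene(head=make_head_phantom(3))
        baseline = ep.render_image(beam, scene, pitch_mm=2.0, panel_shape=(120, 100))
        rates = []
        for roll in (0.5, 1.0):
            _, errant = inject_error(beam, scene, "head_pose", roll_deg=roll)
            img = ep.render_image(beam, errant, pitch_mm=2.0, panel_shape=(120, 100))
            res = ep.gamma_map(
                img,
                baseline,
                ep.ComparisonCriteria(dd_tol_percent=1.0, dta_tol_mm=1.0, mode="gamma"),
            )
            rates.append(res.passing_rate)
        assert rates[1] < rates[0]
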
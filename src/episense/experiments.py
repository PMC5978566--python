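"""Config-driven reproduction of the nine error-injection experiments.

Each scenario renders a nominal (baseline) transit image once, renders one
errant image per induced magnitude, applies the scenario's comparison or
tolerance-descent sweep, and assembles a report row per magnitude:

==================== =============================================== ========
scenario             induced error                                   analysis
==================== =============================================== ========
jaw_shift            one jaw opened 1..4 mm at isocenter             DTA sweep
mlc_static           designated leaves of a shaped field moved       DTA sweep
collimator_rotation  aperture rotated 1..3 degrees                   DTA sweep
output_error         machine output scaled 0.5..1.5 %                DD sweep
couch_shift          couch strip pattern moved 1..3 mm laterally     DTA sweep
rail_static          couch rail moved into an open static beam       DD map
rail_vmat            rail in the beam for part of an arc composite   DD map
mlc_imrt             leaf errors in a pseudo-IMRT fluence            gamma
head_setup           rigid head-phantom setup errors                 gamma
constancy            repeated nominal deliveries with panel noise    DD map
==================== =============================================== ========

Length errors defined at the isocenter appear magnified by sdd/sad on the
image; every report row carries both the induced and the expected
detector-plane magnitude.  All randomness is governed by explicit seeds, so
re-running a spec reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import __version__
from .comparison import ComparisonCriteria, compare, dd_map, gamma_map
from .dose_image import DEFAULT_PITCH_MM, DoseImage, PlaneGeometry, resample_grid
from .simulator import (
    BeamConfig,
    ConfigurationError,
    CouchTop,
    NoiseModel,
    PhantomScene,
    RailState,
    SlabPhantom,
    inject_error,
    make_head_phantom,
    millennium120,
    open_field,
    render_image,
)
from .sweep import collimator_edge_deviation, sweep_dd, sweep_dta

__all__ = [
    "SCENARIOS",
    "ExperimentSpec",
    "ExperimentReport",
    "run_experiment",
    "three_way_comparison",
    "report_render",
    "mlc_shaped_field",
    "HEAD_SETUP_ERRORS",
]

SCENARIOS = (
    "jaw_shift",
    "mlc_static",
    "collimator_rotation",
    "output_error",
    "couch_shift",
    "rail_static",
    "rail_vmat",
    "mlc_imrt",
    "head_setup",
    "constancy",
)

#: Default experiment panel: the clinical panel downsampled 2x.  Induced
#: edges live in continuous coordinates, so detection thresholds are
#: pitch-stable; the coarser grid keeps a full suite at desk scale.
EXPERIMENT_PITCH_MM = 2.0 * DEFAULT_PITCH_MM
EXPERIMENT_PANEL = (384, 512)

#: The six head-phantom setup errors, ordered from least to most severe:
#: (lateral shift mm, longitudinal shift mm, roll deg).
HEAD_SETUP_ERRORS = (
    (0.0, 0.0, 0.5),
    (1.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (1.0, 1.0, 0.5),
    (2.0, 2.0, 0.0),
    (2.0, 2.0, 1.0),
)

_DEFAULT_MAGNITUDES = {
    "jaw_shift": [1.0, 2.0, 3.0, 4.0],
    "mlc_static": [1.0, 2.0, 3.0, 4.0, 5.0],
    "collimator_rotation": [1.0, 2.0, 3.0],
    "output_error": [0.5, 1.0, 1.5],
    "couch_shift": [1.0, 2.0, 3.0],
    "rail_static": [1.0],
    "rail_vmat": [1.0],
    "mlc_imrt": [1.0, 2.0],
    "head_setup": list(range(1, 7)),
    "constancy": [1.0],
}


@dataclass
class ExperimentSpec:
    """One experiment: a scenario id, its induced magnitudes, the
    comparison/sweep parameters, and all sources of randomness."""

    scenario: str
    magnitudes: list[float] | None = None
    geometry: PlaneGeometry = dataclass_field(default_factory=PlaneGeometry)
    pitch_mm: float = EXPERIMENT_PITCH_MM
    panel_shape: tuple[int, int] = EXPERIMENT_PANEL
    sweep_step: float = 0.1
    threshold_percent: float = 10.0
    dd_tol_percent: float = 2.0
    dta_tol_mm: float = 2.0
    noise_sigma: float = 0.0
    seed: int = 0
    min_fail_pixels: int = 1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; valid: {', '.join(SCENARIOS)}"
            )
        if self.magnitudes is None:
            self.magnitudes = list(_DEFAULT_MAGNITUDES[self.scenario])

    def config_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "magnitudes": self.magnitudes,
            "sad_mm": self.geometry.sad_mm,
            "sdd_mm": self.geometry.sdd_mm,
            "pitch_mm": self.pitch_mm,
            "panel_shape": list(self.panel_shape),
            "sweep_step": self.sweep_step,
            "threshold_percent": self.threshold_percent,
            "dd_tol_percent": self.dd_tol_percent,
            "dta_tol_mm": self.dta_tol_mm,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "min_fail_pixels": self.min_fail_pixels,
        }


@dataclass
class ExperimentReport:
    """Per-magnitude result rows plus reproducibility provenance."""

    scenario: str
    rows: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "rows": self.rows, "provenance": self.provenance}

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentReport":
        return cls(data["scenario"], list(data["rows"]), dict(data["provenance"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ---------------------------------------------------------------------------
# field builders


def mlc_shaped_field(mu: float = 100.0) -> BeamConfig:
    """The 13 cm x 5 cm MLC-shaped static field with predetermined leaf
    positions: jaws at 13 x 5 cm, ten 5 mm central leaf pairs open with a
    gently varying outline."""
    mlc = millennium120(left_mm=0.0, right_mm=0.0)
    # Leaf pairs covering y in [-25, 25] mm at isocenter: indices 25..34.
    open_pairs = np.arange(25, 35)
    for rank, i in enumerate(open_pairs):
        mlc.left_positions_mm[i] = -65.0 + 6.0 * abs(math.sin(0.9 * rank))
        mlc.right_positions_mm[i] = 65.0 - 6.0 * abs(math.cos(0.7 * rank))
    return BeamConfig(jaws_mm=(65.0, 65.0, 25.0, 25.0), mlc=mlc, mu=mu)


def _pseudo_imrt_segments(rng: np.random.Generator, n_min: int = 5, n_max: int = 10):
    """Seeded pseudo-IMRT fluence: 5-10 rectangular MLC segments of a
    10 x 10 cm field, each a (BeamConfig, relative MU weight)."""
    n_seg = int(rng.integers(n_min, n_max + 1))
    segments = []
    for _ in range(n_seg):
        mlc = millennium120(left_mm=0.0, right_mm=0.0)
        lo = rng.uniform(-50.0, 0.0)
        hi = rng.uniform(5.0, 50.0)
        y_lo = rng.uniform(-50.0, -5.0)
        y_hi = rng.uniform(5.0, 50.0)
        for i in range(mlc.n_pairs):
            b_lo, b_hi = mlc.leaf_boundaries_mm[i], mlc.leaf_boundaries_mm[i + 1]
            if b_hi > y_lo and b_lo < y_hi:
                mlc.left_positions_mm[i] = lo
                mlc.right_positions_mm[i] = hi
        beam = BeamConfig(jaws_mm=(50.0, 50.0, 50.0, 50.0), mlc=mlc, mu=100.0)
        segments.append((beam, float(rng.uniform(0.5, 1.5))))
    return segments


def _render_composite(segments, scene, spec: ExperimentSpec, noise_seed: int) -> DoseImage:
    """MU-weighted sum of static renders (the planar stand-in for an arc or
    a step-and-shoot sequence); noise is applied once to the composite."""
    total = None
    weight_sum = sum(w for _, w in segments)
    for beam, w in segments:
        img = render_image(
            beam,
            scene,
            None,
            spec.geometry,
            spec.pitch_mm,
            spec.panel_shape,
        )
        vals = img.values * (w / weight_sum)
        total = vals if total is None else total + vals
        template = img
    out = DoseImage(total, template.pixel_pitch_mm, template.plane_sdd_mm, template.origin)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        out.values = np.clip(
            out.values * (1.0 + spec.noise_sigma * rng.standard_normal(out.values.shape)),
            0.0,
            None,
        )
    return out


def _render(spec: ExperimentSpec, beam, scene, seed_offset: int = 0) -> DoseImage:
    noise = (
        NoiseModel(spec.noise_sigma, spec.seed + seed_offset)
        if spec.noise_sigma > 0
        else None
    )
    return render_image(
        beam, scene, noise, spec.geometry, spec.pitch_mm, spec.panel_shape
    )


# ---------------------------------------------------------------------------
# scenario implementations


def _sweep_row(
    spec: ExperimentSpec,
    baseline: DoseImage,
    errant: DoseImage,
    induced_iso: float,
    expected_det: float,
    mode: str,
) -> dict:
    start = math.ceil((expected_det + 0.5) / spec.sweep_step) * spec.sweep_step
    if mode == "dta":
        sw = sweep_dta(
            baseline,
            errant,
            start_mm=start,
            step_mm=spec.sweep_step,
            threshold_percent=spec.threshold_percent,
            induced_mm=expected_det,
            min_fail_pixels=spec.min_fail_pixels,
        )
    else:
        sw = sweep_dd(
            baseline,
            errant,
            start_percent=start,
            step_percent=spec.sweep_step,
            threshold_percent=spec.threshold_percent,
            induced_percent=expected_det,
            min_fail_pixels=spec.min_fail_pixels,
        )
    return {
        "induced": induced_iso,
        "expected_detector": expected_det,
        "detection_threshold": sw.detection_threshold,
        "sensitivity": sw.sensitivity,
        "n_fail_at_detection": sw.trace[-1][1] if sw.trace else 0,
    }


def _run_geometry_sweeps(spec: ExperimentSpec) -> list[dict]:
    m = spec.geometry.magnification
    rows = []
    if spec.scenario == "jaw_shift":
        nominal = open_field(10.0, 10.0)
        scene = None
        baseline = _render(spec, nominal, scene)
        for mag in spec.magnitudes:
            beam, sc = inject_error(nominal, scene, "jaw_shift", jaw="X1", shift_mm=mag)
            errant = _render(spec, beam, sc, seed_offset=1)
            rows.append(_sweep_row(spec, baseline, errant, mag, mag * m, "dta"))
    elif spec.scenario == "mlc_static":
        nominal = mlc_shaped_field()
        baseline = _render(spec, nominal, None)
        leaves = [25, 29, 33]  # every 4th open leaf on the left bank
        for mag in spec.magnitudes:
            beam, sc = inject_error(
                nominal, None, "mlc_shift", leaves=leaves, bank="left", shift_mm=mag
            )
            errant = _render(spec, beam, sc, seed_offset=1)
            rows.append(_sweep_row(spec, baseline, errant, mag, mag * m, "dta"))
    elif spec.scenario == "collimator_rotation":
        nominal = open_field(10.0, 10.0)
        baseline = _render(spec, nominal, None)
        field_side_det = 100.0 * m
        for mag in spec.magnitudes:
            beam, sc = inject_error(nominal, None, "collimator_rotation", angle_deg=mag)
            errant = _render(spec, beam, sc, seed_offset=1)
            expected = round(collimator_edge_deviation(field_side_det, mag), 1)
            rows.append(_sweep_row(spec, baseline, errant, mag, expected, "dta"))
    elif spec.scenario == "couch_shift":
        nominal = open_field(10.0, 10.0)
        scene = PhantomScene(couch=CouchTop())
        baseline = _render(spec, nominal, scene)
        for mag in spec.magnitudes:
            beam, sc = inject_error(nominal, scene, "couch_shift", lateral_mm=mag)
            errant = _render(spec, beam, sc, seed_offset=1)
            rows.append(_sweep_row(spec, baseline, errant, mag, mag * m, "dta"))
    elif spec.scenario == "output_error":
        nominal = open_field(10.0, 10.0)
        scene = PhantomScene(slab=SlabPhantom(thickness_cm=10.0))
        baseline = _render(spec, nominal, scene)
        for mag in spec.magnitudes:
            beam, sc = inject_error(nominal, scene, "output_error", percent=mag)
            errant = _render(spec, beam, sc, seed_offset=1)
            rows.append(_sweep_row(spec, baseline, errant, mag, mag, "dd"))
    return rows


def _run_rail(spec: ExperimentSpec) -> list[dict]:
    if spec.scenario == "rail_static":
        beam = open_field(18.0, 18.0)
        beam.gantry_label = "G45"
        scene_out = PhantomScene(couch=CouchTop(), rail=RailState(position="out"))
        baseline = _render(spec, beam, scene_out)
        _, scene_in = inject_error(beam, scene_out, "rail_state", position="in")
        errant = _render(spec, beam, scene_in, seed_offset=1)
        res = dd_map(
            errant,
            baseline,
            ComparisonCriteria(
                dd_tol_percent=1.0, mode="dd_only", threshold_percent=spec.threshold_percent
            ),
        )
        return [
            {
                "induced": "rail in vs out",
                "max_abs_dd_percent": res.max_abs_dd,
                "n_fail": res.n_fail,
                "passing_rate": res.passing_rate,
            }
        ]
    # VMAT proxy: an MU-weighted composite of 8 static control points; the
    # rail band sits in the beam for 3 of them in the errant delivery.
    beam = open_field(10.0, 10.0)
    n_cp = 8
    rail_out = PhantomScene(couch=CouchTop(), rail=RailState(position="out"))
    _, rail_in = inject_error(beam, rail_out, "rail_state", position="in")
    base_segments = [(beam, 1.0)] * n_cp
    baseline = _render_composite(
        [(b, w) for b, w in base_segments], rail_out, spec, spec.seed
    )
    total = None
    for idx in range(n_cp):
        scene = rail_in if idx < 3 else rail_out
        img = render_image(beam, scene, None, spec.geometry, spec.pitch_mm, spec.panel_shape)
        vals = img.values / n_cp
        total = vals if total is None else total + vals
        template = img
    errant = DoseImage(total, template.pixel_pitch_mm, template.plane_sdd_mm, template.origin)
    res = dd_map(
        errant,
        baseline,
        ComparisonCriteria(
            dd_tol_percent=1.0, mode="dd_only", threshold_percent=spec.threshold_percent
        ),
    )
    return [
        {
            "induced": "rail in for 3/8 control points",
            "max_abs_dd_percent": res.max_abs_dd,
            "n_fail": res.n_fail,
            "passing_rate": res.passing_rate,
        }
    ]


def _run_mlc_imrt(spec: ExperimentSpec) -> list[dict]:
    rng = np.random.default_rng(spec.seed)
    segments = _pseudo_imrt_segments(rng)
    scene = PhantomScene(slab=SlabPhantom(thickness_cm=20.0))
    baseline = _render_composite(segments, scene, spec, spec.seed + 100)
    rows = []
    for mag in spec.magnitudes:
        errant_segments = []
        for beam, w in segments:
            eb, _ = inject_error(
                beam, None, "mlc_shift", leaves=list(range(10, 50, 4)), bank="left", shift_mm=mag
            )
            errant_segments.append((eb, w))
        errant = _render_composite(errant_segments, scene, spec, spec.seed + 101)
        res = gamma_map(
            errant,
            baseline,
            ComparisonCriteria(
                dd_tol_percent=spec.dd_tol_percent,
                dta_tol_mm=spec.dta_tol_mm,
                mode="gamma",
                threshold_percent=spec.threshold_percent,
            ),
        )
        rows.append(
            {
                "induced": mag,
                "expected_detector": mag * spec.geometry.magnification,
                "passing_rate": res.passing_rate,
                "max_abs_dd_percent": res.max_abs_dd,
            }
        )
    return rows


def _run_head_setup(spec: ExperimentSpec) -> list[dict]:
    head = make_head_phantom(spec.seed)
    beam = open_field(9.0, 11.5)
    scene = PhantomScene(head=head)
    baseline = _render(spec, beam, scene)
    rows = []
    for rank, (lat, lng, roll) in enumerate(HEAD_SETUP_ERRORS, start=1):
        _, errant_scene = inject_error(
            beam, scene, "head_pose", lateral_mm=lat, longitudinal_mm=lng, roll_deg=roll
        )
        errant = _render(spec, beam, errant_scene, seed_offset=rank)
        row = {
            "induced": f"{lat:g} mm shifts, {roll:g} deg roll",
            "severity_rank": rank,
            "lateral_mm": lat,
            "longitudinal_mm": lng,
            "roll_deg": roll,
        }
        for tol in (1.0, 2.0, 3.0):
            res = gamma_map(
                errant,
                baseline,
                ComparisonCriteria(
                    dd_tol_percent=tol,
                    dta_tol_mm=tol,
                    mode="gamma",
                    threshold_percent=spec.threshold_percent,
                ),
            )
            row[f"passing_rate_{tol:g}/{tol:g}"] = res.passing_rate
        rows.append(row)
    return rows


def _run_constancy(spec: ExperimentSpec, n_repeats: int = 4) -> list[dict]:
    sigma = spec.noise_sigma if spec.noise_sigma > 0 else 0.001
    beam = open_field(10.0, 10.0)
    images = [
        render_image(
            beam,
            None,
            NoiseModel(sigma, spec.seed + k),
            spec.geometry,
            spec.pitch_mm,
            spec.panel_shape,
        )
        for k in range(n_repeats)
    ]
    max_dd = 0.0
    for a in range(n_repeats):
        for b in range(a + 1, n_repeats):
            res = dd_map(
                images[b],
                images[a],
                ComparisonCriteria(
                    dd_tol_percent=0.2, mode="dd_only", threshold_percent=spec.threshold_percent
                ),
            )
            max_dd = max(max_dd, res.max_abs_dd)
    return [
        {
            "induced": f"{n_repeats} nominal repeats, sigma={sigma:g}",
            "noise_sigma": sigma,
            "max_pairwise_abs_dd_percent": max_dd,
            "within_0.2_percent": bool(max_dd <= 0.2),
        }
    ]


def run_experiment(spec: ExperimentSpec) -> ExperimentReport:
    """Render baseline and errant images for one scenario and analyse them.

    Fully deterministic given ``spec.seed``.
    """
    if spec.scenario in (
        "jaw_shift",
        "mlc_static",
        "collimator_rotation",
        "couch_shift",
        "output_error",
    ):
        rows = _run_geometry_sweeps(spec)
    elif spec.scenario in ("rail_static", "rail_vmat"):
        rows = _run_rail(spec)
    elif spec.scenario == "mlc_imrt":
        rows = _run_mlc_imrt(spec)
    elif spec.scenario == "head_setup":
        rows = _run_head_setup(spec)
    else:
        rows = _run_constancy(spec)
    config = spec.config_dict()
    digest = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    provenance = {"config": config, "config_hash": digest, "seed": spec.seed, "version": __version__}
    return ExperimentReport(spec.scenario, rows, provenance)


# ---------------------------------------------------------------------------
# three-way cross-grid comparison


def three_way_comparison(
    *pairs: tuple[DoseImage, DoseImage],
    criteria: ComparisonCriteria | None = None,
) -> dict:
    """Gamma passing rates of several (baseline, errant) representations of
    the same fields on possibly different grids, plus their maximum spread.

    Coarse representations (e.g. a 5 mm diode array) are resampled to the
    finest pitch present before the per-pair gamma analysis, the analogue
    of bringing a planning-system calculation, an array measurement and a
    portal image onto a common grid.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (baseline, errant) representations")
    if criteria is None:
        criteria = ComparisonCriteria(dd_tol_percent=2.0, dta_tol_mm=2.0, mode="gamma")
    fine = min(ref.pixel_pitch_mm for ref, _ in pairs)
    rates = []
    for ref, ev in pairs:
        if ref.pixel_pitch_mm > fine * (1 + 1e-9):
            ref = resample_grid(ref, fine)
            ev = resample_grid(ev, fine)
        rates.append(compare(ev, ref, criteria).passing_rate)
    spread = max(rates) - min(rates)
    return {"passing_rates": rates, "max_spread": spread}


# ---------------------------------------------------------------------------
# report serialization


def report_render(report: ExperimentReport, path: str, format: str = "json") -> None:
    """Write a report: lossless JSON, or a CSV / markdown projection of the
    row table."""
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    elif format == "csv":
        report.to_frame().to_csv(path, index=False)
    elif format == "markdown":
        frame = report.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# Scenario: {report.scenario}\n\n")
            fh.write(frame.to_markdown(index=False))
            fh.write(
                f"\n\nconfig_hash: {report.provenance['config_hash']}  "
                f"seed: {report.provenance['seed']}\n"
            )
    else:
        raise ValueError(f"unknown report format {format!r}")
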
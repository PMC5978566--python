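"""Independent brute-force reference implementations used as oracles.

These deliberately share no code with the package's search algorithms:
the DTA oracle runs an exhaustive level-crossing scan over a dense global
refinement of the baseline, the gamma oracle an exhaustive vectorised
minimisation over every offset of the refinement lattice.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from episense import DoseImage


def node_match_tolerance(ref: np.ndarray, floor: float) -> np.ndarray:
    """Per-node dose tolerance: bilinear interpolation error bound
    (local second differences / 8) with an absolute floor."""
    d2r = np.pad(np.abs(np.diff(ref, n=2, axis=0)), ((1, 1), (0, 0)), mode="edge")
    d2c = np.pad(np.abs(np.diff(ref, n=2, axis=1)), ((0, 0), (1, 1)), mode="edge")
    return np.maximum(
        (
            ndimage.maximum_filter(d2r, 3, mode="nearest")
            + ndimage.maximum_filter(d2c, 3, mode="nearest")
        )
        / 8.0,
        floor,
    )


def dta_brute_force(
    eval_img: DoseImage,
    ref_img: DoseImage,
    radius_mm: float = 6.0,
    step_mm: float = 0.04,
    threshold_percent: float = 10.0,
) -> np.ndarray:
    """Exhaustive DTA: distance to sign-change crossings of the bilinearly
    refined baseline, plus node matches within the interpolation-error
    tolerance; +inf where the level is not found within the radius."""
    ref = ref_img.values
    norm = ref.max()
    pitch = ref_img.pixel_pitch_mm
    floor = 2.0 ** -16 * norm
    ntol = node_match_tolerance(ref, floor)
    ny, nx = ref.shape
    f = int(round(pitch / step_mm))
    fp = pitch / f
    rows = np.arange(0, (ny - 1) * f + 1) / f
    cols = np.arange(0, (nx - 1) * f + 1) / f
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    fine = ndimage.map_coordinates(ref, [rr, cc], order=1)
    out = np.zeros_like(ref)
    nodes_r, nodes_c = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for i in range(ny):
        for j in range(nx):
            if ref[i, j] < threshold_percent / 100.0 * norm:
                continue
            v = eval_img.values[i, j]
            if abs(v - ref[i, j]) <= floor:
                continue
            s = fine - v
            best = np.inf
            with np.errstate(invalid="ignore", divide="ignore"):
                pr, pc = np.nonzero(s[:-1, :] * s[1:, :] <= 0)
                if pr.size:
                    t = np.nan_to_num(s[pr, pc] / (s[pr, pc] - s[pr + 1, pc]))
                    best = min(
                        best,
                        (((pr + t) * fp - i * pitch) ** 2 + (pc * fp - j * pitch) ** 2).min(),
                    )
                qr, qc = np.nonzero(s[:, :-1] * s[:, 1:] <= 0)
                if qr.size:
                    t = np.nan_to_num(s[qr, qc] / (s[qr, qc] - s[qr, qc + 1]))
                    best = min(
                        best,
                        ((qr * fp - i * pitch) ** 2 + ((qc + t) * fp - j * pitch) ** 2).min(),
                    )
            near = np.abs(ref - v) <= ntol
            if near.any():
                best = min(
                    best,
                    (
                        ((nodes_r[near] - i) * pitch) ** 2
                        + ((nodes_c[near] - j) * pitch) ** 2
                    ).min(),
                )
            out[i, j] = np.sqrt(best) if best <= radius_mm ** 2 else np.inf
    return out


def gamma_brute_force(
    eval_img: DoseImage,
    ref_img: DoseImage,
    dd_percent: float,
    dta_mm: float,
    threshold_percent: float = 10.0,
    step_mm: float = 0.025,
    radius_mm: float = 4.0,
) -> np.ndarray:
    """Exhaustive gamma: full minimisation over every lattice offset within
    the search radius, baseline interpolated bilinearly."""
    ref = ref_img.values
    norm = ref.max()
    dd_abs = dd_percent / 100.0 * norm
    pitch = ref_img.pixel_pitch_mm
    k = int(radius_mm / step_mm)
    off = np.arange(-k, k + 1) * step_mm
    dy, dx = np.meshgrid(off, off, indexing="ij")
    rr0 = dy.ravel()
    cc0 = dx.ravel()
    r2 = rr0 ** 2 + cc0 ** 2
    keep = r2 <= radius_mm ** 2 + 1e-12
    rr0, cc0, r2 = rr0[keep] / pitch, cc0[keep] / pitch, r2[keep]
    out = np.zeros_like(ref)
    ny, nx = ref.shape
    with np.errstate(invalid="ignore"):
        for i in range(ny):
            for j in range(nx):
                if ref[i, j] < threshold_percent / 100.0 * norm:
                    continue
                ref_q = ndimage.map_coordinates(
                    ref, [i + rr0, j + cc0], order=1, mode="constant", cval=np.nan
                )
                g2 = r2 / dta_mm ** 2 + ((eval_img.values[i, j] - ref_q) / dd_abs) ** 2
                out[i, j] = np.sqrt(np.nanmin(g2))
    return out


def bump_field(
    seed: int,
    n: int = 40,
    pitch_mm: float = 0.78125,
    shift_mm: tuple[float, float] = (0.0, 0.0),
) -> DoseImage:
    """Smooth random dose field: a seeded mixture of Gaussian bumps over a
    uniform base, sampled analytically so a shifted copy is an exact
    translation (no resampling artefacts)."""
    rng = np.random.default_rng(seed)
    y = (np.arange(n) + 0.5) * pitch_mm
    x = (np.arange(n) + 0.5) * pitch_mm
    xx, yy = np.meshgrid(x, y)
    v = np.full((n, n), 40.0)
    for _ in range(6):
        cx, cy = rng.uniform(0, n * pitch_mm, 2)
        s = rng.uniform(5, 9)
        a = rng.uniform(-25, 25)
        v = v + a * np.exp(
            -(((xx - shift_mm[0]) - cx) ** 2 + ((yy - shift_mm[1]) - cy) ** 2) / (2 * s * s)
        )
    return DoseImage(np.clip(v, 1.0, None), pitch_mm, 1500.0, (n / 2, n / 2))
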
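"""Ground-truthed synthetic data for every stage of the analysis.

Three generators, all pure functions of their parameters and a seed:

* :func:`simulate_micrograph` renders SEM-like micrographs of spray-dried
  microcapsules — shaded disks with a log-normal (right-skewed, unimodal)
  diameter population, optional border-crossing particles, pairwise overlap
  control, Gaussian sensor noise, and an instrument databar strip with a
  white scale bar — together with a per-particle ground-truth table.
* :func:`simulate_assay_replicates` draws triplicate bench measurements
  from Normal(true mean, replicate SD) per formulation.
* :func:`simulate_peak_areas` produces chromatographic peak areas from a
  linear response model with additive noise.

The defaults emulate the study conditions the analysis targets: 20 µm per
229 px spatial calibration, a 65-row databar, and a particle population
with median 3.7 µm and log-SD 0.45 (most particles < 6 µm, tail to
~12–14 µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlacementError
from . import reference

__all__ = [
    "MicrographSimParams",
    "AssaySimParams",
    "simulate_micrograph",
    "simulate_assay_replicates",
    "simulate_peak_areas",
    "write_micrograph",
]


@dataclass
class MicrographSimParams:
    """Parameters for one simulated micrograph.

    ``image_width`` / ``image_height`` describe the content region, to which
    ``databar_height`` rows of databar are appended at the bottom.  Diameters
    are drawn from a log-normal with the given median (µm) and log-SD.
    ``max_overlap_fraction`` is the allowed overlap of a new disk with any
    placed disk, as a fraction of the smaller disk's area (0 = disjoint,
    with a ``min_gap_px`` pixel cushion so disjoint disks stay 8-disconnected).
    """

    n_particles: int = 100
    image_width: int = 1024
    image_height: int = 1024
    databar_height: int = reference.DATABAR_CROP_ROWS
    scalebar_px: int = reference.SCALEBAR_PX
    scalebar_um: float = reference.SCALEBAR_UM
    median_um: float = reference.PARTICLE_MEDIAN_UM
    sigma_log: float = reference.PARTICLE_LOG_SD
    allow_border: bool = True
    max_overlap_fraction: float = 0.0
    min_gap_px: float = 2.0
    background_level: int = 30
    particle_level: int = 220
    noise_sd: float = 8.0
    seed: int = 0
    max_attempts: int = 5000

    def __post_init__(self):
        if min(self.image_width, self.image_height) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.databar_height < 0:
            raise ValueError("databar_height must be >= 0")
        if not (self.scalebar_px > 0 and self.scalebar_um > 0):
            raise ValueError("scale bar lengths must be positive")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if not self.median_um > 0:
            raise ValueError("diameter distribution median must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if not (0 <= self.max_overlap_fraction < 1):
            raise ValueError("max_overlap_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def um_per_px(self) -> float:
        return self.scalebar_um / self.scalebar_px


@dataclass
class AssaySimParams:
    """Replicate noise model for one formulation and one assay."""

    true_mean: float
    replicate_sd: float
    n_replicates: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two disks with radii r1, r2 and center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * np.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return a1 + a2 - tri


def simulate_micrograph(params: MicrographSimParams):
    """Render a micrograph and return ``(Micrograph, ground_truth)``.

    The ground truth is a DataFrame with one row per rendered particle:
    ``id, row, col, diameter_um, touches_border, fully_visible``.
    ``touches_border`` is true iff the rendered pixel extent of the disk
    touches the first/last row or column of the content region.  Identical
    parameters (including seed) give identical image and truth.

    Raises :class:`~capmetrics.errors.PlacementError` if rejection sampling
    cannot place all particles under the overlap constraint.
    """
    from .imaging import Micrograph  # local import avoids cycle at init

    p = params
    rng = np.random.default_rng(p.seed)
    H, W = p.image_height, p.image_width
    content = np.full((H, W), float(p.background_level))

    diam_um = rng.lognormal(mean=np.log(p.median_um), sigma=p.sigma_log,
                            size=p.n_particles)
    radii_px = diam_um / p.um_per_px / 2.0
    # Place largest first: improves packing feasibility without changing the
    # marginal diameter distribution.
    order = np.argsort(-radii_px)

    placed_r: list[float] = []
    placed_c: list[float] = []
    placed_rad: list[float] = []
    placed_idx: list[int] = []
    for idx in order:
        r = float(radii_px[idx])
        ok = False
        for _ in range(p.max_attempts):
            if p.allow_border:
                row = rng.uniform(0, H - 1)
                col = rng.uniform(0, W - 1)
            else:
                if 2 * r + 2 >= min(H, W):
                    break  # cannot fit an interior disk this large
                row = rng.uniform(r + 1, H - 2 - r)
                col = rng.uniform(r + 1, W - 2 - r)
            accept = True
            for rr, cc, rad in zip(placed_r, placed_c, placed_rad):
                d = np.hypot(row - rr, col - cc)
                if p.max_overlap_fraction == 0.0:
                    if d < r + rad + p.min_gap_px:
                        accept = False
                        break
                else:
                    lens = _lens_area(d, r, rad)
                    if lens > p.max_overlap_fraction * np.pi * min(r, rad) ** 2:
                        accept = False
                        break
            if accept:
                ok = True
                break
        if not ok:
            raise PlacementError(len(placed_idx), p.n_particles)
        placed_r.append(row)
        placed_c.append(col)
        placed_rad.append(r)
        placed_idx.append(int(idx))

    touches = []
    for row, col, r in zip(placed_r, placed_c, placed_rad):
        r0, r1 = max(0, int(np.floor(row - r))), min(H - 1, int(np.ceil(row + r)))
        c0, c1 = max(0, int(np.floor(col - r))), min(W - 1, int(np.ceil(col + r)))
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        rho = np.hypot(yy - row, xx - col)
        inside = rho <= r
        if inside.any():
            # Linear radial shading: brightest at the center, mimicking
            # secondary-electron contrast on a smooth sphere.
            shade = p.background_level + (p.particle_level - p.background_level) * (
                1.0 - 0.45 * rho / max(r, 1e-9)
            )
            patch = content[r0 : r1 + 1, c0 : c1 + 1]
            patch[inside] = np.maximum(patch[inside], shade[inside])
            rows_in, cols_in = np.nonzero(inside)
            touch = (
                (rows_in + r0).min() == 0
                or (rows_in + r0).max() == H - 1
                or (cols_in + c0).min() == 0
                or (cols_in + c0).max() == W - 1
            )
        else:
            touch = False
        touches.append(bool(touch))

    if p.noise_sd > 0:
        content = content + rng.normal(0.0, p.noise_sd, size=content.shape)
    content = np.clip(np.rint(content), 0, 255).astype(np.uint8)

    if p.databar_height > 0:
        databar = np.full((p.databar_height, W), 90, dtype=np.uint8)
        bar_len = min(p.scalebar_px, W - 40)
        bar_row = p.databar_height // 2
        thickness = min(5, p.databar_height)
        databar[bar_row : bar_row + thickness, 20 : 20 + bar_len] = 255
        full = np.vstack([content, databar])
    else:
        full = content

    truth = pd.DataFrame(
        {
            "id": np.arange(len(placed_idx)),
            "row": placed_r,
            "col": placed_c,
            "diameter_um": [diam_um[i] for i in placed_idx],
            "touches_border": touches,
        }
    )
    # With zero allowed overlap, every interior particle is fully visible.
    if p.max_overlap_fraction == 0.0:
        truth["fully_visible"] = ~truth["touches_border"]
    else:
        occluded = _any_overlap(placed_r, placed_c, placed_rad)
        truth["fully_visible"] = ~(truth["touches_border"] | occluded)

    img = Micrograph(
        full,
        bit_depth=8,
        databar_height=p.databar_height,
        scalebar_px=p.scalebar_px,
        scalebar_um=p.scalebar_um,
    )
    return img, truth


def _any_overlap(rows, cols, rads) -> np.ndarray:
    n = len(rows)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(rows[i] - rows[j], cols[i] - cols[j]) < rads[i] + rads[j]:
                out[i] = out[j] = True
    return out


def simulate_assay_replicates(
    params_by_formulation: dict[str, AssaySimParams],
    seed: int | None = 0,
) -> pd.DataFrame:
    """Triplicate (by default) bench measurements per formulation.

    Returns a tidy frame ``(formulation, replicate, value)``.  Per-formulation
    seeds (if set on the params) override the global *seed*; otherwise each
    formulation gets an independent child stream of *seed* so adding a
    formulation does not perturb the others' draws.
    """
    if not params_by_formulation:
        raise ValueError("at least one formulation is required")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(params_by_formulation))
    frames = []
    for (label, p), child in zip(params_by_formulation.items(), children):
        rng = np.random.default_rng(p.seed if p.seed is not None else child)
        values = rng.normal(p.true_mean, p.replicate_sd, size=p.n_replicates)
        frames.append(
            pd.DataFrame(
                {
                    "formulation": label,
                    "replicate": np.arange(1, p.n_replicates + 1),
                    "value": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_peak_areas(
    amounts_ng,
    curve=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_rt: float = reference.REFERENCE_RT_MIN,
    rt_sd: float = 0.02,
) -> pd.DataFrame:
    """Chromatographic peak areas from a linear response model.

    ``area = slope * amount + intercept + Normal(0, noise_sd)``; retention
    times are drawn near *reference_rt*.  *curve* is anything with ``slope``
    and ``intercept`` attributes (defaults to the bundled lutein calibration).
    Returns a peak table ``(retention_time, area, amount_ng)`` — the last
    column is the truth channel.
    """
    amounts = np.asarray(amounts_ng, dtype=float)
    if np.any(amounts < 0):
        raise ValueError("amounts must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    slope = reference.CALIBRATION_SLOPE if curve is None else curve.slope
    intercept = reference.CALIBRATION_INTERCEPT if curve is None else curve.intercept
    rng = np.random.default_rng(seed)
    areas = slope * amounts + intercept
    if noise_sd > 0:
        areas = areas + rng.normal(0.0, noise_sd, size=amounts.shape)
    rts = reference_rt + rng.normal(0.0, rt_sd, size=amounts.shape)
    return pd.DataFrame(
        {"retention_time": rts, "area": areas, "amount_ng": amounts}
    )


def write_micrograph(path, img, truth: pd.DataFrame | None = None,
                     truth_path=None) -> None:
    """Write a micrograph as single-page 8-bit grayscale TIFF, and the
    ground truth (if given) as CSV."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(img.pixels, dtype=np.uint8))
    if truth is not None and truth_path is not None:
        truth.to_csv(truth_path, index=False)
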
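"""Synthetic cell-swell imaging assay: image generation, segmentation, area
measurement and normalized time-course summaries.

Round chondrocytes are modeled as bright disks on a dark background.  After a
switch from iso-osmotic to hypo-osmotic bath at t = 0 the cross-sectional
area follows a saturating-exponential swell

    A(t)/A(0) = 1 + (P - 1) * (1 - exp(-t / tau_rise)) - RVD(t)

toward a plateau relative area P (about 1.06-1.11 over 5 min in these
cohorts), optionally opposed by a slower regulatory-volume-decrease (RVD)
term.  Measured areas are per-cell normalized to the pre-challenge frame, so
each cell is its own control and absolute calibration cancels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .stats import mean_ci, mc_dunnett

__all__ = [
    "SwellModel",
    "SwellTimecourse",
    "relative_area",
    "generate_cell_stack",
    "measure_area",
    "measure_stack",
    "normalize_timecourse",
    "generate_cohort",
    "summarize_groups",
    "fit_swell_timecourse",
    "write_stack",
    "read_stack",
]


@dataclass
class SwellModel:
    """Generating model for one cell's swell time course and image stack."""

    initial_area_um2: float = 875.0
    plateau_relative_area: float = 1.06
    rise_tau_s: float = 90.0
    rvd_fraction: float = 0.0  # fraction of the swell amplitude recovered by RVD
    rvd_tau_s: float = 600.0
    frame_interval_s: float = 60.0
    n_frames: int = 6  # t = 0 (pre-challenge) through 5 min
    um_per_px: float = 0.25
    frame_shape: tuple[int, int] = (192, 192)
    area_jitter_frac: float = 0.01  # per-frame multiplicative area jitter (sd)
    pixel_noise_frac: float = 0.05  # Gaussian pixel noise, sd as fraction of contrast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_relative_area < 1.0:
            raise ValueError("plateau relative area must be >= 1")
        if self.rise_tau_s <= 0 or self.rvd_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.rvd_fraction <= 1.0:
            raise ValueError("rvd fraction must lie in [0, 1]")
        if self.initial_area_um2 <= 0:
            raise ValueError("initial area must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def relative_area(model: SwellModel, t_s) -> np.ndarray:
    """Ground-truth relative cross-sectional area at time t (1.0 before t = 0)."""
    t = np.asarray(t_s, dtype=float)
    amp = model.plateau_relative_area - 1.0
    swell = amp * (1.0 - np.exp(-np.maximum(t, 0.0) / model.rise_tau_s))
    rvd = model.rvd_fraction * amp * (1.0 - np.exp(-np.maximum(t, 0.0) / model.rvd_tau_s))
    return 1.0 + swell - rvd


def generate_cell_stack(model: SwellModel) -> tuple[np.ndarray, dict]:
    """Render a grayscale frame stack of one swelling disk-shaped cell.

    Returns the stack (n_frames, H, W, float32 in [0, ~1]) and a ground-truth
    dict with times, true relative areas and true areas in um^2.  The disk
    edge is anti-aliased (sub-pixel coverage) so segmentation bias stays well
    below the swell amplitude.
    """
    rng = np.random.default_rng(model.seed)
    h, w = model.frame_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx)

    rel = relative_area(model, model.times_s)
    # per-frame area jitter models focus/boundary wobble of the measured cell
    jitter = 1.0 + model.area_jitter_frac * rng.standard_normal(model.n_frames)
    jitter[0] = 1.0  # the pre-challenge frame defines the reference area
    true_rel = rel * jitter
    r0_um = float(np.sqrt(model.initial_area_um2 / np.pi))
    radii_px = r0_um * np.sqrt(true_rel) / model.um_per_px
    if np.max(radii_px) + 2.0 > min(h, w) / 2.0:
        raise ValueError(
            f"disk radius {np.max(radii_px):.1f} px exceeds the "
            f"{model.frame_shape} frame; enlarge the frame or shrink the cell"
        )

    frames = np.empty((model.n_frames, h, w), dtype=np.float32)
    for i, r in enumerate(radii_px):
        disk = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        noise = model.pixel_noise_frac * rng.standard_normal((h, w))
        frames[i] = (disk + noise).astype(np.float32)

    truth = {
        "times_s": model.times_s.tolist(),
        "relative_area": true_rel.tolist(),
        "area_um2": (model.initial_area_um2 * true_rel).tolist(),
        "radius_px": radii_px.tolist(),
        "model": asdict(model),
    }
    return frames, truth


def measure_area(frame: np.ndarray, um_per_px: float) -> float:
    """Cross-sectional area (um^2) of the dominant bright object in a frame.

    Otsu threshold -> largest connected component -> pixel count x scale^2.
    """
    frame = np.asarray(frame, dtype=float)
    if float(np.ptp(frame)) < 1e-9:
        raise ValueError("frame is flat: no foreground object to segment")
    mask = frame > threshold_otsu(frame)
    if not mask.any():
        raise ValueError("no foreground object above the Otsu threshold")
    regions = regionprops(label(mask))
    largest = max(regions, key=lambda r: r.area)
    return float(largest.area) * um_per_px**2


def measure_stack(stack: np.ndarray, um_per_px: float) -> np.ndarray:
    return np.array([measure_area(f, um_per_px) for f in stack])


@dataclass
class SwellTimecourse:
    """Normalized cross-sectional area of one cell over the osmotic challenge."""

    cell_id: str
    group: str
    time_s: np.ndarray
    normalized_area: np.ndarray
    initial_area_um2: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.normalized_area = np.asarray(self.normalized_area, dtype=float)
        if self.normalized_area[0] != 1.0:
            raise ValueError("normalized area must equal 1 at the reference frame")
        if np.any(self.normalized_area <= 0):
            raise ValueError("areas must be positive")


def normalize_timecourse(
    areas_um2,
    times_s,
    cell_id: str = "",
    group: str = "",
) -> SwellTimecourse:
    """Normalize a measured area series to its pre-challenge (t <= 0) frame."""
    areas = np.asarray(areas_um2, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if times[0] > 0:
        raise ValueError("first frame must be pre-challenge (t <= 0)")
    if areas[0] <= 0:
        raise ValueError("pre-challenge area must be positive")
    return SwellTimecourse(
        cell_id=cell_id,
        group=group,
        time_s=times,
        normalized_area=areas / areas[0],
        initial_area_um2=float(areas[0]),
    )


def generate_cohort(
    group: str,
    n_cells: int,
    base: SwellModel,
    amplitude_jitter_frac: float = 0.35,
    initial_area_jitter_frac: float = 0.05,
    seed: int = 0,
) -> list[SwellModel]:
    """Per-cell models for one group: the cohort-mean swell amplitude and
    initial area are jittered between cells (seeded), emulating biological
    spread around the group means."""
    rng = np.random.default_rng(seed)
    amp = base.plateau_relative_area - 1.0
    models = []
    for i in range(n_cells):
        cell_amp = max(amp * (1.0 + amplitude_jitter_frac * rng.standard_normal()), 0.0)
        area = base.initial_area_um2 * (
            1.0 + initial_area_jitter_frac * rng.standard_normal()
        )
        models.append(
            replace(
                base,
                plateau_relative_area=1.0 + cell_amp,
                initial_area_um2=max(area, 50.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return models


def summarize_groups(
    courses: list[SwellTimecourse],
    t_eval_s: float = 300.0,
    control_group: str = "control",
    n_draws: int = 100_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-group mean normalized area at ``t_eval_s`` with t-based 95 % CIs and
    Monte-Carlo Dunnett comparisons against the control group."""
    values: dict[str, list[float]] = {}
    for c in courses:
        j = int(np.argmin(np.abs(c.time_s - t_eval_s)))
        if abs(c.time_s[j] - t_eval_s) > np.median(np.diff(c.time_s)) / 2:
            raise ValueError(f"no frame near t = {t_eval_s} s for cell {c.cell_id}")
        values.setdefault(c.group, []).append(float(c.normalized_area[j]))
    if control_group not in values:
        raise ValueError(f"control group {control_group!r} missing")
    treatment_names = [g for g in values if g != control_group]
    rows = []
    ctrl = np.array(values[control_group])
    m, lo, hi = mean_ci(ctrl)
    rows.append(
        {"group": control_group, "mean": m, "ci_low": lo, "ci_high": hi,
         "n": ctrl.size, "p_raw": np.nan, "p_dunnett": np.nan}
    )
    if treatment_names:
        res = mc_dunnett(
            [np.array(values[g]) for g in treatment_names],
            ctrl,
            n_draws=n_draws,
            seed=seed,
        )
        for g, praw, padj in zip(treatment_names, res.raw_pvalues, res.pvalues):
            m, lo, hi = mean_ci(np.array(values[g]))
            rows.append(
                {"group": g, "mean": m, "ci_low": lo, "ci_high": hi,
                 "n": len(values[g]), "p_raw": praw, "p_dunnett": padj}
            )
    return pd.DataFrame(rows)


def fit_swell_timecourse(times_s, normalized_area) -> tuple[float, float]:
    """Recover (plateau relative area, rise tau) from a normalized time course
    by least squares on the saturating-exponential swell model (RVD off)."""
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(normalized_area, dtype=float)

    def f(t, plateau, tau):
        return 1.0 + (plateau - 1.0) * (1.0 - np.exp(-np.maximum(t, 0.0) / tau))

    p, _ = curve_fit(
        f, t, y, p0=[max(y.max(), 1.001), 90.0],
        bounds=([1.0, 1.0], [3.0, 3000.0]), maxfev=10000,
    )
    return float(p[0]), float(p[1])


def write_stack(stack: np.ndarray, truth: dict, tiff_path: str | Path) -> None:
    """Multi-page TIFF plus a JSON ground-truth side-car."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(stack, dtype=np.float32))
    tiff_path.with_suffix(".json").write_text(json.dumps(truth, indent=2) + "\n")


def read_stack(tiff_path: str | Path) -> tuple[np.ndarray, dict]:
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    truth = json.loads(tiff_path.with_suffix(".json").read_text())
    return stack, truth
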
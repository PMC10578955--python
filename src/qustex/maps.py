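"""Sliding-window parametric maps and ROI-level statistics.

The window geometry follows a 2 x 2 mm block with 94.1 % overlap between
adjacent windows in both directions; at the default acquisition geometry
this works out to steps of 1 scan line laterally and 6 samples axially.
A window contributes a map pixel when its *center* pixel lies inside the
ROI mask (windows may overhang the ROI edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from qustex.core import (
    QUS_PARAMETER_UNITS,
    QUS_PARAMETERS,
    ParametricMap,
    RFFrame,
)
from qustex.spectral import (
    AnalysisBand,
    AttenuationModel,
    compute_window_spectrum,
    fit_form_factor,
    fit_spectral_line,
    normalize_spectrum,
)

log = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window block size and overlap for map construction."""

    window_size_mm: float = 2.0
    overlap_fraction: float = 0.941
    min_lines_per_window: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_size_mm <= 0:
            raise ValueError("window size must be positive")

    def window_pixels(self, spacing_mm: float) -> int:
        return max(1, _round_half_up(self.window_size_mm / spacing_mm))

    def step_pixels(self, spacing_mm: float) -> int:
        win = self.window_pixels(spacing_mm)
        return max(1, _round_half_up((1.0 - self.overlap_fraction) * win))


def window_lattice(n_pixels: int, win: int, step: int) -> np.ndarray:
    """Start indices of every full window along one axis."""
    if n_pixels < win:
        return np.empty(0, dtype=int)
    return np.arange(0, n_pixels - win + 1, step)


def average_phantom_spectrum(phantom: RFFrame,
                             cfg: SlidingWindowConfig | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Average window spectrum of a phantom recording.

    Uses the same window geometry as map construction (so the frequency
    grid matches sample windows bin for bin) with non-overlapping tiling
    for speed.
    """
    cfg = cfg or SlidingWindowConfig()
    acq = phantom.acquisition
    win_ax = cfg.window_pixels(acq.axial_sample_spacing_cm * 10.0)
    win_lat = max(cfg.window_pixels(acq.lateral_line_spacing_cm * 10.0),
                  cfg.min_lines_per_window)
    rows = window_lattice(phantom.n_samples, win_ax, win_ax)
    cols = window_lattice(phantom.n_lines, win_lat, win_lat)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("phantom smaller than one window")
    freqs, acc = None, None
    count = 0
    for r0 in rows:
        for c0 in cols:
            f, p = compute_window_spectrum(
                phantom.samples[r0:r0 + win_ax, c0:c0 + win_lat],
                acq.sampling_rate)
            acc = p if acc is None else acc + p
            freqs = f
            count += 1
    return freqs, acc / count


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    p_value_one_tail: float


def build_parametric_maps(frame: RFFrame,
                          mask: np.ndarray,
                          phantom_spectrum: tuple[np.ndarray, np.ndarray],
                          reference_bsc: tuple[np.ndarray, np.ndarray],
                          cfg: SlidingWindowConfig | None = None,
                          band: AnalysisBand | None = None,
                          atten: AttenuationModel | None = None,
                          models: tuple[str, ...] = ("gaussian", "anderson"),
                          ) -> dict[str, ParametricMap]:
    """Build the seven spectral parameter maps over an ROI.

    Parameters
    ----------
    frame
        RF frame to analyse.
    mask
        Boolean ROI mask on the RF sample grid (axial x lines).
    phantom_spectrum
        Reference power spectrum per window geometry: a callable is not
        required -- the same (freqs, power) grid is used for every
        window, as produced by averaging a large phantom recording with
        the identical window length.
    reference_bsc
        (freqs_mhz, value) analytic backscatter curve of the phantom.
    """
    cfg = cfg or SlidingWindowConfig()
    band = band or AnalysisBand()
    atten = atten or AttenuationModel(local_attenuation=frame.attenuation_db_cm_mhz)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.samples.shape:
        raise ValueError("mask shape must match RF samples")
    if not mask.any():
        raise ValueError("ROI too small: empty mask")

    acq = frame.acquisition
    ax_spacing_mm = acq.axial_sample_spacing_cm * 10.0
    lat_spacing_mm = acq.lateral_line_spacing_cm * 10.0
    win_ax = cfg.window_pixels(ax_spacing_mm)
    win_lat = max(cfg.window_pixels(lat_spacing_mm), cfg.min_lines_per_window)
    step_ax = cfg.step_pixels(ax_spacing_mm)
    step_lat = cfg.step_pixels(lat_spacing_mm)

    rows = window_lattice(frame.n_samples, win_ax, step_ax)
    cols = window_lattice(frame.n_lines, win_lat, step_lat)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("ROI too small: window does not fit in frame")

    shape = (rows.size, cols.size)
    values = {p: np.full(shape, np.nan) for p in QUS_PARAMETERS}
    validity = np.zeros(shape, dtype=bool)
    n_failed = 0

    for ri, r0 in enumerate(rows):
        depth_cm = frame.depth_of_sample(r0 + win_ax // 2)
        for ci, c0 in enumerate(cols):
            if not mask[r0 + win_ax // 2, c0 + win_lat // 2]:
                continue
            window = frame.samples[r0:r0 + win_ax, c0:c0 + win_lat]
            try:
                sample_ps = compute_window_spectrum(window, acq.sampling_rate)
                ns = normalize_spectrum(sample_ps, phantom_spectrum, atten,
                                        depth_cm, band=band)
                line = fit_spectral_line(ns, band)
                values["MBF"][ri, ci] = line.MBF
                values["SS"][ri, ci] = line.SS
                values["SI"][ri, ci] = line.SI
                for model in models:
                    bf = fit_form_factor(ns, reference_bsc, band, model=model,
                                         c=acq.speed_of_sound)
                    values[f"ASD_{model}"][ri, ci] = bf.ASD
                    values[f"AAC_{model}"][ri, ci] = bf.AAC
                validity[ri, ci] = True
            except ValueError as exc:
                n_failed += 1
                log.debug("window (%d, %d) failed: %s", r0, c0, exc)

    if not validity.any():
        raise ValueError("ROI too small: no valid window positions")
    if n_failed:
        log.info("%d window fits failed and were invalidated", n_failed)

    spacing = (step_ax * ax_spacing_mm, step_lat * lat_spacing_mm)
    return {
        p: ParametricMap(parameter_id=p,
                         values=np.where(validity, values[p], np.nan),
                         validity_mask=validity & np.isfinite(values[p]),
                         pixel_spacing=spacing,
                         units=QUS_PARAMETER_UNITS[p])
        for p in QUS_PARAMETERS
    }


def roi_mean(pmap: ParametricMap) -> float:
    """Arithmetic mean over valid map pixels."""
    if pmap.n_valid == 0:
        raise ValueError("no valid pixels")
    return float(pmap.valid_values.mean())


def patient_mean(frame_means: list[float]) -> float:
    """Patient-level value: mean of the per-frame ROI means."""
    if not frame_means:
        raise ValueError("no frames")
    return float(np.mean(frame_means))


def compare_groups(values_a: list[float], values_b: list[float],
                   direction: str = "greater") -> GroupComparison:
    """Pooled-variance two-sample t test, one-tailed.

    ``direction="greater"`` tests mean(a) > mean(b).  Two constant,
    identical groups give p = 0.5 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        p = 0.5
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True,
                                  alternative=direction).pvalue)
    return GroupComparison(mean_a=float(a.mean()), mean_b=float(b.mean()),
                           p_value_one_tail=p)
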
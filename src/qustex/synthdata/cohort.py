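"""Labelled synthetic cohorts of parametric-map ensembles.

Per-patient maps are drawn from class-conditional Gaussian random fields
(mean shifts and spatial-correlation-length shifts between the two
outcome classes), with elliptical ROI masks of randomized size.  This is
deliberately much cheaper than a full RF simulation per patient; the RF
path is validated separately by the spectral recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from qustex.core import (
    QUS_PARAMETER_UNITS,
    QUS_PARAMETERS,
    FrameRecord,
    ParametricMap,
)

log = logging.getLogger(__name__)

#: Baseline (non-responder-like) map means and between-pixel SDs.
BASE_PARAMS = {
    "MBF": (0.6, 3.0),
    "SS": (-2.1, 0.5),
    "SI": (12.0, 4.0),
    "ASD_gaussian": (78.0, 10.0),
    "AAC_gaussian": (61.0, 8.0),
    "ASD_anderson": (137.0, 12.0),
    "AAC_anderson": (107.0, 8.0),
}

#: Mean shifts added for the complete-responder class (direction: CR
#: higher MBF / SI / AAC), plus a correlation-length shift in pixels.
DEFAULT_CLASS_EFFECT = {
    "MBF": 2.8,
    "SS": -0.1,
    "SI": 3.5,
    "ASD_gaussian": 4.8,
    "AAC_gaussian": 2.7,
    "ASD_anderson": 6.2,
    "AAC_anderson": 6.2,
    "corr_length": 0.8,
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic labelled cohort."""

    n_patients: int = 72
    frames_per_patient: int = 6
    class_fraction_cr: float = 0.347
    class_effect: dict = field(default_factory=dict)  # empty = no signal
    seed: int = 0
    map_shape: tuple[int, int] = (32, 32)
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8)
    base_corr_length: float = 2.0  # pixels
    roi_axes_mm: tuple[float, float] = (8.0, 20.0)  # full-axis range
    min_roi_pixels: int = 9  # one 3x3 texture window

    def __post_init__(self) -> None:
        if not 0 < self.class_fraction_cr < 1:
            raise ValueError("class_fraction_cr must be in (0, 1)")
        if self.frames_per_patient < 1:
            raise ValueError("frames_per_patient must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _grf(shape: tuple[int, int], corr_length: float,
         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field via Gaussian smoothing."""
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        field_ = ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")
    else:
        field_ = noise
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _elliptical_mask(shape: tuple[int, int], spacing_mm: tuple[float, float],
                     axes_mm: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    a_mm = rng.uniform(*axes_mm) / 2.0  # semi-axes
    b_mm = rng.uniform(*axes_mm) / 2.0
    cy = h / 2.0 + rng.uniform(-h / 8.0, h / 8.0)
    cx = w / 2.0 + rng.uniform(-w / 8.0, w / 8.0)
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) * spacing_mm[0]
    dx = (xx - cx) * spacing_mm[1]
    return (dy / a_mm) ** 2 + (dx / b_mm) ** 2 <= 1.0


def _frame_maps(spec: CohortSpec, is_cr: bool,
                rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    effect = spec.class_effect
    corr = spec.base_corr_length + (effect.get("corr_length", 0.0) if is_cr else 0.0)
    for _attempt in range(50):
        mask = _elliptical_mask(spec.map_shape, spec.pixel_spacing_mm,
                                spec.roi_axes_mm, rng)
        if mask.sum() >= spec.min_roi_pixels:
            break
        log.info("degenerate ROI (%d px) rejected, regenerating", mask.sum())
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("could not draw a usable ROI")
    maps = {}
    for pid in QUS_PARAMETERS:
        mean, sd = BASE_PARAMS[pid]
        if is_cr:
            mean += effect.get(pid, 0.0)
        values = mean + sd * _grf(spec.map_shape, corr, rng)
        values = np.where(mask, values, np.nan)
        maps[pid] = ParametricMap(parameter_id=pid, values=values,
                                  validity_mask=mask,
                                  pixel_spacing=spec.pixel_spacing_mm,
                                  units=QUS_PARAMETER_UNITS[pid])
    return maps, mask


def generate_synthetic_cohort(spec: CohortSpec) -> list[FrameRecord]:
    """Generate a labelled cohort of per-frame parametric-map sets.

    Label counts follow ``round(class_fraction_cr * n_patients)`` CR
    patients; assignment to patient ids is a seeded permutation.
    """
    rng = np.random.default_rng(spec.seed)
    n_cr = int(round(spec.class_fraction_cr * spec.n_patients))
    labels = np.array(["CR"] * n_cr + ["PR"] * (spec.n_patients - n_cr))
    rng.shuffle(labels)

    frames: list[FrameRecord] = []
    for p in range(spec.n_patients):
        patient_id = f"P{p + 1:03d}"
        label = str(labels[p])
        for fi in range(spec.frames_per_patient):
            maps, _mask = _frame_maps(spec, label == "CR", rng)
            frames.append(FrameRecord(patient_id=patient_id, frame_index=fi,
                                      maps=maps, label=label,
                                      path=f"{patient_id}_f{fi}.h5"))
    return frames


def cohort_manifest(frames: list[FrameRecord]) -> pd.DataFrame:
    """Manifest with one row per frame record."""
    return pd.DataFrame(
        [{"patient_id": f.patient_id, "frame_index": f.frame_index,
          "path": f.path, "label": f.label} for f in frames]
    )


def cohort_labels(frames: list[FrameRecord]) -> pd.Series:
    """Per-patient labels extracted from frame records."""
    out = {}
    for f in frames:
        out[f.patient_id] = f.label
    return pd.Series(out, name="label").sort_index()
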
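"""Shared domain types used across the acquisition, spectral and map stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Soft-tissue speed of sound used for depth <-> sample conversion, m/s.
SPEED_OF_SOUND = 1540.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Transducer / digitizer geometry of an RF acquisition.

    Defaults reproduce a 10 MHz linear probe sampled at 40 MHz with 256
    scan lines over a 3.8 cm lateral field of view and 5 cm depth.
    """

    sampling_rate: float = 40e6          # Hz
    num_lines: int = 256
    lateral_fov: float = 3.8             # cm
    max_depth: float = 5.0               # cm
    pulse_center_frequency: float = 10e6  # Hz
    pulse_fractional_bandwidth: float = 0.6
    speed_of_sound: float = SPEED_OF_SOUND  # m/s

    def __post_init__(self) -> None:
        if self.num_lines < 1:
            raise ValueError("num_lines must be >= 1")
        if self.sampling_rate <= 0 or self.max_depth <= 0 or self.lateral_fov <= 0:
            raise ValueError("geometry values must be positive")

    @property
    def axial_sample_spacing_cm(self) -> float:
        """Pulse-echo axial spacing per sample, cm."""
        return self.speed_of_sound * 100.0 / (2.0 * self.sampling_rate)

    @property
    def lateral_line_spacing_cm(self) -> float:
        return self.lateral_fov / self.num_lines

    @property
    def n_axial_samples(self) -> int:
        return int(round(self.max_depth / self.axial_sample_spacing_cm))


@dataclass
class RFFrame:
    """One frame of digitized echo lines (axial sample x scan line)."""

    samples: np.ndarray
    acquisition: AcquisitionSpec
    focal_depth: float = 1.75  # cm
    attenuation_db_cm_mhz: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (axial x lines)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def depth_of_sample(self, row: int) -> float:
        """One-way depth of an axial sample index, cm."""
        return row * self.acquisition.axial_sample_spacing_cm


@dataclass
class ParametricMap:
    """2-D image of one parameter with a validity mask and pixel spacing.

    ``values`` is NaN wherever ``validity_mask`` is False.
    """

    parameter_id: str
    values: np.ndarray
    validity_mask: np.ndarray
    pixel_spacing: tuple[float, float]  # (axial, lateral) mm / pixel
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values and validity_mask shapes differ")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        if not np.all(np.isfinite(self.values[self.validity_mask])):
            raise ValueError("non-finite values inside validity mask")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.validity_mask]

    @property
    def n_valid(self) -> int:
        return int(self.validity_mask.sum())


@dataclass
class FrameRecord:
    """One cohort frame: the per-frame parametric maps plus bookkeeping."""

    patient_id: str
    frame_index: int
    maps: dict[str, ParametricMap]
    label: str  # "CR" or "PR"
    path: str = ""


#: Canonical identifiers of the seven spectral parameter maps.
QUS_PARAMETERS = (
    "MBF",
    "SS",
    "SI",
    "ASD_gaussian",
    "AAC_gaussian",
    "ASD_anderson",
    "AAC_anderson",
)

QUS_PARAMETER_UNITS = {
    "MBF": "dB",
    "SS": "dB/MHz",
    "SI": "dB",
    "ASD_gaussian": "um",
    "AAC_gaussian": "dB/cm^3",
    "ASD_anderson": "um",
    "AAC_anderson": "dB/cm^3",
}
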
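"""Point-scatterer RF speckle simulation.

Each scan line is synthesized in the frequency domain: scatterer
positions come from a homogeneous Poisson process, amplitudes are
zero-mean Gaussian, the scattering spectrum carries the square root of
the size-dependent Gaussian form factor, the pulse is a
Gaussian-modulated sinusoid, and depth- and frequency-dependent
attenuation multiplies each scatterer's spectral amplitude by
``10^(-4 * alpha * f_MHz * z_cm / 20)`` -- the exact inverse of the
point-compensation rule applied at analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qustex.core import AcquisitionSpec, RFFrame
from qustex.spectral import gaussian_form_factor


@dataclass(frozen=True)
class ScattererSpec:
    """Ground-truth scattering population of a simulated medium."""

    effective_diameter: float = 80.0    # um (true ASD)
    number_density: float = 16.0        # scatterers / mm^2
    amplitude_variance: float = 1.0     # arbitrary units (AAC proxy)
    attenuation_coefficient: float = 0.0  # dB/cm/MHz

    def __post_init__(self) -> None:
        if self.effective_diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.number_density <= 0:
            raise ValueError("density must be positive")
        if self.amplitude_variance < 0 or self.attenuation_coefficient < 0:
            raise ValueError("variance and attenuation must be >= 0")


def _pulse_spectrum(freqs_hz: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    """Amplitude spectrum of a Gaussian-modulated sinusoid (-6 dB width
    = fractional bandwidth x center frequency)."""
    fc = acq.pulse_center_frequency
    bw = acq.pulse_fractional_bandwidth * fc
    sigma = bw / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((freqs_hz - fc) ** 2) / (2.0 * sigma ** 2))


def _resolution_cell_mm2(acq: AcquisitionSpec) -> float:
    """Rough pulse-echo resolution cell.

    Axial extent ~ 3x the compressed pulse length c/(2 bw); lateral
    extent ~ 3 line pitches as a crude stand-in for the beamwidth.  Only
    used for the sparse-scatterer warning heuristic.
    """
    fc = acq.pulse_center_frequency
    bw = max(acq.pulse_fractional_bandwidth * fc, 1e3)
    axial_mm = 3.0 * acq.speed_of_sound / (2.0 * bw) * 1e3
    lateral_mm = 3.0 * acq.lateral_line_spacing_cm * 10.0
    return axial_mm * lateral_mm


def simulate_rf_frame(acq: AcquisitionSpec, scat: ScattererSpec,
                      seed: int) -> RFFrame:
    """Simulate one RF frame; ground truth is stored on the frame.

    The ground-truth record carries the true ASD, attenuation, the
    backscatter amplitude proxy (amplitude variance x density) and a
    ``sparse_scatterers`` warning flag when the expected count per
    resolution cell drops below 1.
    """
    rng = np.random.default_rng(seed)
    n_samples = acq.n_axial_samples
    n_freq = n_samples // 2 + 1
    freqs_hz = np.fft.rfftfreq(n_samples, d=1.0 / acq.sampling_rate)
    freqs_mhz = freqs_hz / 1e6

    transfer = _pulse_spectrum(freqs_hz, acq) * np.sqrt(
        gaussian_form_factor(freqs_mhz, scat.effective_diameter,
                             acq.speed_of_sound))

    depth_mm = acq.max_depth * 10.0
    line_width_mm = acq.lateral_line_spacing_cm * 10.0
    mean_per_line = scat.number_density * depth_mm * line_width_mm
    alpha = scat.attenuation_coefficient

    samples = np.zeros((n_samples, acq.num_lines))
    if scat.amplitude_variance > 0:
        amp_sd = np.sqrt(scat.amplitude_variance)
        for line in range(acq.num_lines):
            n_sc = rng.poisson(mean_per_line)
            if n_sc == 0:
                continue
            z_cm = rng.uniform(0.0, acq.max_depth, size=n_sc)
            amps = rng.normal(0.0, amp_sd, size=n_sc)
            t = 2.0 * z_cm / 100.0 / acq.speed_of_sound  # round-trip, s
            phase = np.exp(-2j * np.pi * np.outer(t, freqs_hz))
            if alpha > 0:
                att = 10.0 ** (-4.0 * alpha * np.outer(z_cm, freqs_mhz) / 20.0)
                spec = (amps[:, None] * att * phase).sum(axis=0)
            else:
                spec = (amps[:, None] * phase).sum(axis=0)
            samples[:, line] = np.fft.irfft(spec * transfer, n=n_samples)

    per_cell = scat.number_density * _resolution_cell_mm2(acq) / 1e0
    gt = {
        "ASD": scat.effective_diameter,
        "attenuation_db_cm_mhz": alpha,
        "amplitude_variance": scat.amplitude_variance,
        "number_density": scat.number_density,
        "backscatter_amplitude": scat.amplitude_variance * scat.number_density,
        "sparse_scatterers": bool(per_cell < 1.0),
        "seed": seed,
    }
    return RFFrame(samples=samples, acquisition=acq,
                   attenuation_db_cm_mhz=alpha, ground_truth=gt)


#: Fixed, documented reference-phantom population.
PHANTOM_SCATTERERS = ScattererSpec(effective_diameter=20.0, number_density=32.0,
                                   amplitude_variance=1.0,
                                   attenuation_coefficient=0.0)


def phantom_reference_bsc(freqs_mhz: np.ndarray,
                          c: float = 1540.0) -> np.ndarray:
    """Analytic backscatter-coefficient curve of the reference phantom.

    ``f^4`` Rayleigh dependence times the (near-unity in band) Gaussian
    form factor of the phantom's 20 um scatterers; absolute scale fixed
    at 1 (only relative calibration matters downstream).
    """
    f = np.asarray(freqs_mhz, dtype=float)
    return f ** 4 * gaussian_form_factor(f, PHANTOM_SCATTERERS.effective_diameter, c)


def simulate_reference_phantom(acq: AcquisitionSpec, seed: int
                               ) -> tuple[RFFrame, np.ndarray, np.ndarray]:
    """Simulate the calibration phantom.

    Returns
    -------
    (frame, bsc_freqs_mhz, bsc_values)
        The RF frame plus its analytic backscatter curve sampled on a
        0-20 MHz grid.
    """
    frame = simulate_rf_frame(acq, PHANTOM_SCATTERERS, seed)
    freqs = np.linspace(0.0, 20.0, 401)
    return frame, freqs, phantom_reference_bsc(freqs, acq.speed_of_sound)
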
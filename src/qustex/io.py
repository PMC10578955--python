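"""HDF5 container I/O for RF frames, phantoms and parametric maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from qustex.core import AcquisitionSpec, ParametricMap, RFFrame


def write_rf(path: str | Path, frame: RFFrame, mask: np.ndarray | None = None,
             reference_bsc: tuple[np.ndarray, np.ndarray] | None = None) -> None:
    """Write an RF frame (and optional ROI mask / phantom BSC curve)."""
    acq = frame.acquisition
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=frame.samples.astype(np.float32))
        if mask is not None:
            f.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))
        if reference_bsc is not None:
            freqs, vals = reference_bsc
            f.create_dataset("reference_bsc",
                             data=np.column_stack([freqs, vals]).astype(np.float64))
        f.attrs["sampling_rate_hz"] = acq.sampling_rate
        f.attrs["num_lines"] = acq.num_lines
        f.attrs["lateral_fov_cm"] = acq.lateral_fov
        f.attrs["max_depth_cm"] = acq.max_depth
        f.attrs["pulse_center_frequency_hz"] = acq.pulse_center_frequency
        f.attrs["pulse_fractional_bandwidth"] = acq.pulse_fractional_bandwidth
        f.attrs["speed_of_sound_mps"] = acq.speed_of_sound
        f.attrs["focal_depth_cm"] = frame.focal_depth
        f.attrs["attenuation_db_cm_mhz"] = frame.attenuation_db_cm_mhz
        if frame.ground_truth:
            f.attrs["ground_truth_json"] = json.dumps(frame.ground_truth)


def read_rf(path: str | Path):
    """Read an RF frame; returns (frame, mask_or_None, bsc_or_None)."""
    with h5py.File(path, "r") as f:
        acq = AcquisitionSpec(
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            num_lines=int(f.attrs["num_lines"]),
            lateral_fov=float(f.attrs["lateral_fov_cm"]),
            max_depth=float(f.attrs["max_depth_cm"]),
            pulse_center_frequency=float(f.attrs["pulse_center_frequency_hz"]),
            pulse_fractional_bandwidth=float(f.attrs["pulse_fractional_bandwidth"]),
            speed_of_sound=float(f.attrs["speed_of_sound_mps"]),
        )
        gt = json.loads(f.attrs["ground_truth_json"]) if "ground_truth_json" in f.attrs else {}
        frame = RFFrame(samples=f["rf"][()].astype(float), acquisition=acq,
                        focal_depth=float(f.attrs["focal_depth_cm"]),
                        attenuation_db_cm_mhz=float(f.attrs["attenuation_db_cm_mhz"]),
                        ground_truth=gt)
        mask = f["mask"][()].astype(bool) if "mask" in f else None
        bsc = None
        if "reference_bsc" in f:
            arr = f["reference_bsc"][()]
            bsc = (arr[:, 0], arr[:, 1])
    return frame, mask, bsc


def write_maps(path: str | Path, maps: dict[str, ParametricMap],
               group: str = "maps") -> None:
    """Write parametric maps as ``/<group>/<parameter_id>`` groups."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        root = f.create_group(group)
        for pid, pmap in maps.items():
            g = root.create_group(pid)
            g.create_dataset("values", data=pmap.values.astype(np.float64))
            g.create_dataset("validity", data=pmap.validity_mask.astype(np.uint8))
            g.attrs["pixel_spacing_mm_axial"] = pmap.pixel_spacing[0]
            g.attrs["pixel_spacing_mm_lateral"] = pmap.pixel_spacing[1]
            g.attrs["units"] = pmap.units


def read_maps(path: str | Path, group: str = "maps") -> dict[str, ParametricMap]:
    out = {}
    with h5py.File(path, "r") as f:
        for pid, g in f[group].items():
            out[pid] = ParametricMap(
                parameter_id=pid,
                values=g["values"][()],
                validity_mask=g["validity"][()].astype(bool),
                pixel_spacing=(float(g.attrs["pixel_spacing_mm_axial"]),
                               float(g.attrs["pixel_spacing_mm_lateral"])),
                units=str(g.attrs["units"]),
            )
    return out
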
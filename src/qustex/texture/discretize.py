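"""Min-max gray-level discretization of parametric maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GrayImage:
    """Discretized image with integer levels in ``1..ng`` over valid pixels.

    Invalid pixels are stored as 0 and never participate in pair, run,
    zone or dependence counting.
    """

    levels: np.ndarray  # int array, 0 = invalid, 1..ng = valid
    ng: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.ng < 2:
            raise ValueError("ng must be >= 2")
        valid = self.levels > 0
        if valid.any() and (self.levels[valid] > self.ng).any():
            raise ValueError("levels exceed ng")

    @property
    def valid(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def discretize(values: np.ndarray, ng: int = 16, valid: np.ndarray | None = None,
               provenance: dict | None = None) -> GrayImage:
    """Bin ``values`` into ``ng`` equal-width levels between the valid min and max.

    Parameters
    ----------
    values
        2-D array; NaN entries are treated as invalid.
    ng
        Number of gray levels (>= 2).
    valid
        Optional boolean validity mask; combined with finiteness of ``values``.

    Returns
    -------
    GrayImage
        Levels in ``1..ng`` on valid pixels, 0 elsewhere.  A constant map
        maps every valid pixel to level 1.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if valid is not None:
        mask &= np.asarray(valid, dtype=bool)
    if not mask.any():
        raise ValueError("no valid pixels to discretize")
    vmin = float(values[mask].min())
    vmax = float(values[mask].max())
    levels = np.zeros(values.shape, dtype=np.int64)
    if vmax > vmin:
        scaled = (values[mask] - vmin) / (vmax - vmin)
        lv = np.floor(scaled * ng).astype(np.int64) + 1
        np.clip(lv, 1, ng, out=lv)
        levels[mask] = lv
    else:
        levels[mask] = 1
    prov = dict(provenance or {})
    prov.update({"rule": "equal-width-minmax", "min": vmin, "max": vmax, "ng": ng})
    return GrayImage(levels=levels, ng=ng, provenance=prov)
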
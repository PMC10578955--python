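"""The four 2-D texture-matrix families.

Conventions (fixed, mirrored by the feature formulas):

* GLCM: distance-1 offsets in the four in-plane directions (0, 45, 90,
  135 degrees), symmetrized, counts summed over directions.
* GLRLM: maximal runs of equal level along the same four directions,
  counts summed over directions.
* GLSZM: 8-connected zones of equal level.
* GLDM: per-pixel dependence = number of 8-neighbours that are valid and
  of identical level (tolerance 0); rows are gray levels, columns are
  dependence sizes ``d`` stored at index ``d`` (so column ``j`` means
  ``j`` dependent neighbours, pyradiomics' ``j+1`` convention shifted).

Invalid pixels break pairs, runs, zones and neighbourhoods; they never
act as a gray level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from qustex.texture.discretize import GrayImage

# (drow, dcol) for 0, 45, 90, 135 degrees; distance 1
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class TextureMatrices:
    """Count matrices for one gray image.

    ``glcm``  : (ng, ng) symmetric pair counts, all directions summed.
    ``glrlm`` : (ng, max_run) run counts, all directions summed; column j
                holds runs of length j+1.
    ``glszm`` : (ng, max_zone) zone counts; column j holds zones of size j+1.
    ``gldm``  : (ng, max_dep+1) dependence counts; column j holds pixels
                with exactly j dependent neighbours.
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    n_valid: int
    ng: int


def _glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    out = np.zeros((ng, ng), dtype=np.int64)
    h, w = levels.shape
    for dr, dc in DIRECTIONS:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        a = levels[r0s:r0e, c0s:c0e]
        b = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        ok = (a > 0) & (b > 0)
        if ok.any():
            np.add.at(out, (a[ok] - 1, b[ok] - 1), 1)
    return out + out.T


def _iter_lines(levels: np.ndarray, direction: tuple[int, int]):
    """Yield 1-D arrays of levels along every grid line of a direction."""
    h, w = levels.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        for r in range(h):
            yield levels[r, :]
    elif (dr, dc) == (-1, 0):
        for c in range(w):
            yield levels[:, c]
    elif (dr, dc) == (-1, 1):  # anti-diagonals, traversed up-right
        flipped = levels[::-1, :]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    elif (dr, dc) == (-1, -1):  # main diagonals, traversed up-left
        flipped = levels[:, ::-1][::-1, :]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    else:  # pragma: no cover - fixed direction set
        raise ValueError(f"unsupported direction {direction}")


def _runs(line: np.ndarray):
    """Run-length encode one line; invalid (0) pixels break runs."""
    n = len(line)
    i = 0
    while i < n:
        if line[i] == 0:
            i += 1
            continue
        j = i + 1
        while j < n and line[j] == line[i]:
            j += 1
        yield int(line[i]), j - i
        i = j


def _glrlm(levels: np.ndarray, ng: int) -> np.ndarray:
    max_run = max(levels.shape)
    out = np.zeros((ng, max_run), dtype=np.int64)
    for direction in DIRECTIONS:
        for line in _iter_lines(levels, direction):
            for level, length in _runs(np.asarray(line)):
                out[level - 1, length - 1] += 1
    # trim trailing empty run lengths, keep >= 1 column
    nz = np.nonzero(out.any(axis=0))[0]
    last = nz[-1] + 1 if len(nz) else 1
    return out[:, :last]


def _glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    n_valid = int((levels > 0).sum())
    max_zone = max(n_valid, 1)
    out = np.zeros((ng, max_zone), dtype=np.int64)
    for g in np.unique(levels[levels > 0]):
        lab, nlab = ndimage.label(levels == g, structure=_STRUCT8)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                out[g - 1, s - 1] += 1
    nz = np.nonzero(out.any(axis=0))[0]
    last = nz[-1] + 1 if len(nz) else 1
    return out[:, :last]


def _gldm(levels: np.ndarray, ng: int) -> np.ndarray:
    h, w = levels.shape
    valid = levels > 0
    dep = np.zeros((h, w), dtype=np.int64)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for dr, dc in offsets:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        a = levels[r0s:r0e, c0s:c0e]
        b = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        dep[r0s:r0e, c0s:c0e] += ((a > 0) & (a == b)).astype(np.int64)
    out = np.zeros((ng, 9), dtype=np.int64)
    np.add.at(out, (levels[valid] - 1, dep[valid]), 1)
    nz = np.nonzero(out.any(axis=0))[0]
    last = nz[-1] + 1 if len(nz) else 1
    return out[:, :last]


_FAMILY_BUILDERS = {
    "glcm": _glcm,
    "glrlm": _glrlm,
    "glszm": _glszm,
    "gldm": _gldm,
}


def compute_family_matrix(g: GrayImage, family: str) -> np.ndarray:
    """Compute a single family's count matrix (used by the TOT fast path)."""
    try:
        builder = _FAMILY_BUILDERS[family]
    except KeyError:
        raise KeyError(f"unknown family {family!r}") from None
    return builder(g.levels, g.ng)


def compute_matrices(g: GrayImage) -> TextureMatrices:
    """Compute GLCM, GLRLM, GLSZM and GLDM counts for a gray image."""
    levels = g.levels
    return TextureMatrices(
        glcm=_glcm(levels, g.ng),
        glrlm=_glrlm(levels, g.ng),
        glszm=_glszm(levels, g.ng),
        gldm=_gldm(levels, g.ng),
        n_valid=g.n_valid,
        ng=g.ng,
    )
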
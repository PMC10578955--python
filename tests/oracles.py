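"""Independent brute-force oracles for the texture stage.

Everything here is written as plain exhaustive loops, deliberately
sharing no code or vectorization strategy with the package, so matrix
and feature tests are genuine dual-route checks.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_4 = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
OFFSETS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def o_glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetrized distance-1 co-occurrence counts summed over 4 directions."""
    h, w = levels.shape
    out = np.zeros((ng, ng), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            a = levels[r, c]
            if a == 0:
                continue
            for dr, dc in OFFSETS_4:
                for sign in (1, -1):
                    rr, cc = r + sign * dr, c + sign * dc
                    if 0 <= rr < h and 0 <= cc < w and levels[rr, cc] > 0:
                        out[a - 1, levels[rr, cc] - 1] += 1
    return out


def o_glrlm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Maximal-run counts per level and length, summed over 4 directions."""
    h, w = levels.shape
    runs = []
    for dr, dc in OFFSETS_4:
        for r in range(h):
            for c in range(w):
                a = levels[r, c]
                if a == 0:
                    continue
                pr, pc = r - dr, c - dc
                if 0 <= pr < h and 0 <= pc < w and levels[pr, pc] == a:
                    continue  # not the start of a maximal run
                length = 0
                rr, cc = r, c
                while 0 <= rr < h and 0 <= cc < w and levels[rr, cc] == a:
                    length += 1
                    rr += dr
                    cc += dc
                runs.append((a, length))
    max_len = max((ln for _, ln in runs), default=1)
    out = np.zeros((ng, max_len), dtype=np.int64)
    for lvl, ln in runs:
        out[lvl - 1, ln - 1] += 1
    return out


def o_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """8-connected equal-level zone sizes via explicit flood fill."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            lvl = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in OFFSETS_8:
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < h and 0 <= nc < w and not seen[nr, nc]
                            and levels[nr, nc] == lvl):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones.append((lvl, size))
    max_size = max((s for _, s in zones), default=1)
    out = np.zeros((ng, max_size), dtype=np.int64)
    for lvl, size in zones:
        out[lvl - 1, size - 1] += 1
    return out


def o_gldm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Dependence counts: equal-level 8-neighbours per valid pixel."""
    h, w = levels.shape
    pairs = []
    for r in range(h):
        for c in range(w):
            a = levels[r, c]
            if a == 0:
                continue
            d = 0
            for dr, dc in OFFSETS_8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and levels[rr, cc] == a:
                    d += 1
            pairs.append((a, d))
    max_d = max((d for _, d in pairs), default=0)
    out = np.zeros((ng, max_d + 1), dtype=np.int64)
    for lvl, d in pairs:
        out[lvl - 1, d] += 1
    return out


# ---------------------------------------------------------------------------
# naive feature formulas (plain loops, no shared helpers with the package)


def _log2(v: float) -> float:
    return math.log2(v)


def o_glcm_features(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    n = counts.sum()
    if n == 0:
        return {}
    p = counts / n
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum(px[i] * (i + 1 - mux) ** 2 for i in range(ng)))
    sigy = math.sqrt(sum(py[j] * (j + 1 - muy) ** 2 for j in range(ng)))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hy = -sum(v * _log2(v) for v in py if v > 0)
    hxy = -sum(p[i, j] * _log2(p[i, j]) for i in range(ng) for j in range(ng)
               if p[i, j] > 0)
    hxy1 = -sum(p[i, j] * _log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * _log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if px[i] * py[j] > 0)
    autoc = sum(p[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
    da = sum(k * v for k, v in pdiff.items())
    out = {
        "Autocorrelation": autoc,
        "ClusterProminence": sum(p[i, j] * (i + j + 2 - mux - muy) ** 4
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum(p[i, j] * (i + j + 2 - mux - muy) ** 3
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum(p[i, j] * (i + j + 2 - mux - muy) ** 2
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum(p[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)),
        "Correlation": ((autoc - mux * muy) / (sigx * sigy)
                        if sigx > 0 and sigy > 0 else 1.0),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in pdiff.values() if v > 0),
        "DifferenceVariance": sum(v * (k - da) ** 2 for k, v in pdiff.items()),
        "Id": sum(v / (1 + k) for k, v in pdiff.items()),
        "Idm": sum(v / (1 + k * k) for k, v in pdiff.items()),
        "Idmn": sum(v / (1 + k * k / ng ** 2) for k, v in pdiff.items()),
        "Idn": sum(v / (1 + k / ng) for k, v in pdiff.items()),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(v / (k * k) for k, v in pdiff.items() if k > 0),
        "JointAverage": mux,
        "JointEnergy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MaximumProbability": p.max(),
        "SumEntropy": -sum(v * _log2(v) for v in psum.values() if v > 0),
        "SumSquares": sum(p[i, j] * (i + 1 - mux) ** 2
                          for i in range(ng) for j in range(ng)),
    }
    return out


def _o_size_features(counts: np.ndarray, np_norm: int) -> dict[str, float]:
    """Generic (level, size) family formulas, naive loops."""
    ng, smax = counts.shape
    n = counts.sum()
    if n == 0:
        return {}
    p = counts / n
    mu_i = sum(p[i, j] * (i + 1) for i in range(ng) for j in range(smax))
    mu_j = sum(p[i, j] * (j + 1) for i in range(ng) for j in range(smax))
    return {
        "sre": sum(counts[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(smax)) / n,
        "lre": sum(counts[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(smax)) / n,
        "gln": sum(counts[i, :].sum() ** 2 for i in range(ng)) / n,
        "glnn": sum(counts[i, :].sum() ** 2 for i in range(ng)) / n ** 2,
        "sn": sum(counts[:, j].sum() ** 2 for j in range(smax)) / n,
        "snn": sum(counts[:, j].sum() ** 2 for j in range(smax)) / n ** 2,
        "pct": n / np_norm,
        "glv": sum(p[i, j] * (i + 1 - mu_i) ** 2 for i in range(ng) for j in range(smax)),
        "sv": sum(p[i, j] * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(smax)),
        "ent": -sum(p[i, j] * _log2(p[i, j]) for i in range(ng) for j in range(smax)
                    if p[i, j] > 0),
        "lgle": sum(counts[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(smax)) / n,
        "hgle": sum(counts[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(smax)) / n,
        "slgle": sum(counts[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                     for i in range(ng) for j in range(smax)) / n,
        "shgle": sum(counts[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                     for i in range(ng) for j in range(smax)) / n,
        "llgle": sum(counts[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                     for i in range(ng) for j in range(smax)) / n,
        "lhgle": sum(counts[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                     for i in range(ng) for j in range(smax)) / n,
    }


def o_glrlm_features(counts: np.ndarray, n_valid: int) -> dict[str, float]:
    raw = _o_size_features(counts, 4 * n_valid)
    if not raw:
        return {}
    return {
        "ShortRunEmphasis": raw["sre"], "LongRunEmphasis": raw["lre"],
        "GrayLevelNonUniformity": raw["gln"],
        "GrayLevelNonUniformityNormalized": raw["glnn"],
        "RunLengthNonUniformity": raw["sn"],
        "RunLengthNonUniformityNormalized": raw["snn"],
        "RunPercentage": raw["pct"], "GrayLevelVariance": raw["glv"],
        "RunVariance": raw["sv"], "RunEntropy": raw["ent"],
        "LowGrayLevelRunEmphasis": raw["lgle"],
        "HighGrayLevelRunEmphasis": raw["hgle"],
        "ShortRunLowGrayLevelEmphasis": raw["slgle"],
        "ShortRunHighGrayLevelEmphasis": raw["shgle"],
        "LongRunLowGrayLevelEmphasis": raw["llgle"],
        "LongRunHighGrayLevelEmphasis": raw["lhgle"],
    }


def o_glszm_features(counts: np.ndarray, n_valid: int) -> dict[str, float]:
    raw = _o_size_features(counts, n_valid)
    if not raw:
        return {}
    return {
        "SmallAreaEmphasis": raw["sre"], "LargeAreaEmphasis": raw["lre"],
        "GrayLevelNonUniformity": raw["gln"],
        "GrayLevelNonUniformityNormalized": raw["glnn"],
        "SizeZoneNonUniformity": raw["sn"],
        "SizeZoneNonUniformityNormalized": raw["snn"],
        "ZonePercentage": raw["pct"], "GrayLevelVariance": raw["glv"],
        "ZoneVariance": raw["sv"], "ZoneEntropy": raw["ent"],
        "LowGrayLevelZoneEmphasis": raw["lgle"],
        "HighGrayLevelZoneEmphasis": raw["hgle"],
        "SmallAreaLowGrayLevelEmphasis": raw["slgle"],
        "SmallAreaHighGrayLevelEmphasis": raw["shgle"],
        "LargeAreaLowGrayLevelEmphasis": raw["llgle"],
        "LargeAreaHighGrayLevelEmphasis": raw["lhgle"],
    }


def o_gldm_features(counts: np.ndarray) -> dict[str, float]:
    raw = _o_size_features(counts, max(int(counts.sum()), 1))
    if not raw:
        return {}
    return {
        "SmallDependenceEmphasis": raw["sre"],
        "LargeDependenceEmphasis": raw["lre"],
        "GrayLevelNonUniformity": raw["gln"],
        "DependenceNonUniformity": raw["sn"],
        "DependenceNonUniformityNormalized": raw["snn"],
        "GrayLevelVariance": raw["glv"],
        "DependenceVariance": raw["sv"],
        "DependenceEntropy": raw["ent"],
        "LowGrayLevelEmphasis": raw["lgle"],
        "HighGrayLevelEmphasis": raw["hgle"],
        "SmallDependenceLowGrayLevelEmphasis": raw["slgle"],
        "SmallDependenceHighGrayLevelEmphasis": raw["shgle"],
        "LargeDependenceLowGrayLevelEmphasis": raw["llgle"],
        "LargeDependenceHighGrayLevelEmphasis": raw["lhgle"],
    }


def o_discretize(values: np.ndarray, ng: int) -> np.ndarray:
    """Naive re-binning oracle (half-open bins, top value into last bin)."""
    h, w = values.shape
    out = np.zeros((h, w), dtype=np.int64)
    finite = [values[r, c] for r in range(h) for c in range(w)
              if np.isfinite(values[r, c])]
    lo, hi = min(finite), max(finite)
    for r in range(h):
        for c in range(w):
            v = values[r, c]
            if not np.isfinite(v):
                continue
            if hi == lo:
                out[r, c] = 1
            else:
                b = int((v - lo) / (hi - lo) * ng) + 1
                out[r, c] = min(b, ng)
    return out
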
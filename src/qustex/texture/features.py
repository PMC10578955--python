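"""Texture feature catalogs for the four matrix families.

Feature definitions follow the standard published radiomics formulas with
each count matrix normalized to a probability distribution first.  The
GLCM catalog is the 24 classical features minus the sum-average duplicate
and the maximal correlation coefficient, giving the 22/14/16/16 split.

Zero-safe conventions (each guarded in code):

* empty matrix (no pairs / runs / zones) -> every feature 0;
* entropy of an empty distribution = 0;
* emphasis ratios with a zero denominator = 0;
* GLCM correlation of a zero-variance distribution = 1 (flat region).
"""

from __future__ import annotations

import logging

import numpy as np

from qustex.texture.matrices import TextureMatrices

log = logging.getLogger(__name__)

_EPS = np.spacing(1.0)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

FAMILY_CATALOG = {
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
}

TEXTURE_FEATURE_COUNT = sum(len(v) for v in FAMILY_CATALOG.values())  # 68


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log2(p)))


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """Evaluate the 22-feature GLCM catalog on a symmetric count matrix."""
    total = counts.sum()
    if total == 0:
        log.debug("empty GLCM; zero-convention features")
        return {name: 0.0 for name in GLCM_FEATURES}
    ng = counts.shape[0]
    p = counts / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = _entropy(p.ravel())
    pxpy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz] + _EPS)))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2] + _EPS)))

    autoc = float(np.sum(p * ii * jj))
    diff_avg = float(np.sum(k_diff * p_diff))

    if sig_x > 0 and sig_y > 0:
        correlation = (autoc - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    inv_var_mask = k_diff > 0
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p_diff / (1.0 + k_diff))),
        "Idm": float(np.sum(p_diff / (1.0 + k_diff ** 2))),
        "Idmn": float(np.sum(p_diff / (1.0 + (k_diff ** 2) / ng ** 2))),
        "Idn": float(np.sum(p_diff / (1.0 + k_diff / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p_diff[inv_var_mask] / k_diff[inv_var_mask] ** 2)),
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def _size_family(counts: np.ndarray, n_valid: int, names: dict[str, str]) -> dict[str, float]:
    """Shared (level, size) feature body for GLRLM and GLSZM.

    ``names`` maps generic keys to family-specific feature names.
    """
    total = counts.sum()
    if total == 0:
        return {name: 0.0 for name in names.values()}
    ng, smax = counts.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, smax + 1)[None, :]
    p = counts / total
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    out = {
        names["sre"]: float(np.sum(counts / j ** 2) / total),
        names["lre"]: float(np.sum(counts * j.astype(float) ** 2) / total),
        names["gln"]: float(np.sum(row.astype(float) ** 2) / total),
        names["glnn"]: float(np.sum(row.astype(float) ** 2) / total ** 2),
        names["sn"]: float(np.sum(col.astype(float) ** 2) / total),
        names["snn"]: float(np.sum(col.astype(float) ** 2) / total ** 2),
        names["pct"]: float(total / n_valid) if n_valid else 0.0,
        names["glv"]: float(np.sum(p * (i - mu_i) ** 2)),
        names["sv"]: float(np.sum(p * (j - mu_j) ** 2)),
        names["ent"]: _entropy(p.ravel()),
        names["lgle"]: float(np.sum(counts / i.astype(float) ** 2) / total),
        names["hgle"]: float(np.sum(counts * i.astype(float) ** 2) / total),
        names["slgle"]: float(np.sum(counts / (i.astype(float) ** 2 * j.astype(float) ** 2)) / total),
        names["shgle"]: float(np.sum(counts * i.astype(float) ** 2 / j.astype(float) ** 2) / total),
        names["llgle"]: float(np.sum(counts * j.astype(float) ** 2 / i.astype(float) ** 2) / total),
        names["lhgle"]: float(np.sum(counts * (i.astype(float) * j.astype(float)) ** 2) / total),
    }
    return out


_GLRLM_NAMES = {
    "sre": "ShortRunEmphasis", "lre": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity", "snn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage", "glv": "GrayLevelVariance", "sv": "RunVariance",
    "ent": "RunEntropy", "lgle": "LowGrayLevelRunEmphasis",
    "hgle": "HighGrayLevelRunEmphasis", "slgle": "ShortRunLowGrayLevelEmphasis",
    "shgle": "ShortRunHighGrayLevelEmphasis", "llgle": "LongRunLowGrayLevelEmphasis",
    "lhgle": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "sre": "SmallAreaEmphasis", "lre": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage", "glv": "GrayLevelVariance", "sv": "ZoneVariance",
    "ent": "ZoneEntropy", "lgle": "LowGrayLevelZoneEmphasis",
    "hgle": "HighGrayLevelZoneEmphasis", "slgle": "SmallAreaLowGrayLevelEmphasis",
    "shgle": "SmallAreaHighGrayLevelEmphasis", "llgle": "LargeAreaLowGrayLevelEmphasis",
    "lhgle": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(counts: np.ndarray, n_valid: int) -> dict[str, float]:
    """GLRLM 16-feature catalog.

    Note: GLRLM run percentage uses the per-direction-summed convention,
    total runs / (4 directions x valid pixels).
    """
    vals = _size_family(counts, 4 * n_valid, _GLRLM_NAMES)
    return {name: vals[name] for name in GLRLM_FEATURES}


def glszm_features(counts: np.ndarray, n_valid: int) -> dict[str, float]:
    """GLSZM 16-feature catalog."""
    vals = _size_family(counts, n_valid, _GLSZM_NAMES)
    return {name: vals[name] for name in GLSZM_FEATURES}


def gldm_features(counts: np.ndarray) -> dict[str, float]:
    """GLDM 14-feature catalog; column ``d`` = d dependent neighbours."""
    total = counts.sum()
    if total == 0:
        return {name: 0.0 for name in GLDM_FEATURES}
    ng, dmax = counts.shape
    i = np.arange(1, ng + 1)[:, None]
    # dependence size indexed from 1 (d dependent neighbours -> j = d + 1),
    # matching the reference radiomics convention
    j = np.arange(1, dmax + 1)[None, :]
    p = counts / total
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    mu_j = float(np.sum(p * j))
    return {
        "DependenceEntropy": _entropy(p.ravel()),
        "DependenceNonUniformity": float(np.sum(col.astype(float) ** 2) / total),
        "DependenceNonUniformityNormalized": float(np.sum(col.astype(float) ** 2) / total ** 2),
        "DependenceVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(row.astype(float) ** 2) / total),
        "GrayLevelVariance": float(np.sum(p * (i - float(np.sum(p * i))) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(counts * i.astype(float) ** 2) / total),
        "LargeDependenceEmphasis": float(np.sum(counts * j.astype(float) ** 2) / total),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(counts * (i.astype(float) * j.astype(float)) ** 2) / total),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(counts * j.astype(float) ** 2 / i.astype(float) ** 2) / total),
        "LowGrayLevelEmphasis": float(np.sum(counts / i.astype(float) ** 2) / total),
        "SmallDependenceEmphasis": float(np.sum(counts / j.astype(float) ** 2) / total),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(counts * i.astype(float) ** 2 / j.astype(float) ** 2) / total),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(counts / (i.astype(float) ** 2 * j.astype(float) ** 2)) / total),
    }


def compute_texture_features(m: TextureMatrices, prefix: str = "") -> dict[str, float]:
    """Evaluate the full 68-feature catalog on one set of matrices.

    Keys are ``<prefix><family>_<Feature>`` (prefix typically
    ``"<map id>_"``).
    """
    out: dict[str, float] = {}
    for family, vals in (
        ("glcm", glcm_features(m.glcm)),
        ("gldm", gldm_features(m.gldm)),
        ("glrlm", glrlm_features(m.glrlm, m.n_valid)),
        ("glszm", glszm_features(m.glszm, m.n_valid)),
    ):
        for name, value in vals.items():
            out[f"{prefix}{family}_{name}"] = value
    return out


def single_feature(m: TextureMatrices, family: str, name: str) -> float:
    """Evaluate one named feature (used by the texture-of-texture maps)."""
    return single_feature_from_matrix(
        getattr(m, family), family, name, m.n_valid)


def single_feature_from_matrix(counts, family: str, name: str,
                               n_valid: int) -> float:
    """Evaluate one named feature from a single family count matrix."""
    if family == "glcm":
        return glcm_features(counts)[name]
    if family == "gldm":
        return gldm_features(counts)[name]
    if family == "glrlm":
        return glrlm_features(counts, n_valid)[name]
    if family == "glszm":
        return glszm_features(counts, n_valid)[name]
    raise KeyError(f"unknown family {family!r}")
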
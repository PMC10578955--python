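"""First-order (intensity-distribution) features of a parametric map ROI."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

_EPS = np.spacing(1.0)

FIRST_ORDER_FEATURES = (
    "Energy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(values: np.ndarray, ng: int = 16,
                         prefix: str = "") -> dict[str, float]:
    """Evaluate the 17 default first-order features.

    Parameters
    ----------
    values
        1-D or 2-D array; non-finite entries are dropped.
    ng
        Bin count for the histogram-based Entropy and Uniformity.

    Notes
    -----
    Percentiles use linear interpolation (so the 90th percentile of
    ``1..100`` is 90.1).  Robust MAD is the mean absolute deviation from
    the mean of the values inside the closed 10th-90th percentile range.
    Skewness and kurtosis of a constant input are 0 by convention;
    kurtosis is the plain (non-excess) fourth standardized moment.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no valid values")
    mean = float(x.mean())
    var = float(x.var())
    p10, p90 = (float(v) for v in np.percentile(x, [10, 90]))
    p25, p75 = (float(v) for v in np.percentile(x, [25, 75]))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        log.debug("constant first-order input; skewness/kurtosis set to 0")
        skew = 0.0
        kurt = 0.0

    # histogram features on ng equal-width bins over the value range
    if x.max() > x.min():
        counts, _ = np.histogram(x, bins=ng, range=(x.min(), x.max()))
        p = counts / x.size
    else:
        p = np.array([1.0])
    pz = p[p > 0]
    entropy = float(-np.sum(pz * np.log2(pz)))
    uniformity = float(np.sum(pz ** 2))

    out = {
        "Energy": float(np.sum(x ** 2)),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
    return {f"{prefix}firstorder_{k}": v for k, v in out.items()}
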
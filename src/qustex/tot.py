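"""Texture-of-texture (TOT) parametric maps and higher-order features.

A TOT map replaces each pixel of a source parametric map by one named
texture feature evaluated on the pixel's odd-sized sliding window
(default 3x3).  The source map is discretized once globally so every
patch shares a common gray scale; only pixels whose full neighbourhood
is valid get a TOT value.  Features of the TOT maps (first-order plus
the four matrix families, freshly discretized) join the five generating
features to form the enhanced dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from qustex.core import FrameRecord, ParametricMap
from qustex.texture.dataset import CohortDataset, map_texture_features
from qustex.texture.discretize import GrayImage, discretize
from qustex.texture.features import FAMILY_CATALOG, single_feature_from_matrix
from qustex.texture.matrices import compute_family_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TOTMapSpec:
    """One TOT map: a source map id plus a (family, feature) pair."""

    source_parameter: str
    family: str
    feature: str
    window: int = 3
    ng: int = 16

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.family not in FAMILY_CATALOG:
            raise ValueError(f"unknown family {self.family!r}")
        if self.feature not in FAMILY_CATALOG[self.family]:
            raise ValueError(f"unknown feature {self.family}/{self.feature}")

    @property
    def feature_id(self) -> str:
        return f"{self.source_parameter}_{self.family}_{self.feature}"


def parse_feature_id(feature_id: str) -> TOTMapSpec:
    """Parse ``<map>_<family>_<Feature>`` into a TOT map spec."""
    for family in FAMILY_CATALOG:
        token = f"_{family}_"
        if token in feature_id:
            source, feature = feature_id.split(token, 1)
            return TOTMapSpec(source_parameter=source, family=family,
                              feature=feature)
    raise ValueError(f"cannot parse feature id {feature_id!r}")


def build_tot_map(qus_map: ParametricMap, spec: TOTMapSpec) -> ParametricMap:
    """Evaluate one named texture feature on every full window of a map."""
    g = discretize(qus_map.values, ng=spec.ng, valid=qus_map.validity_mask)
    levels = g.levels
    h, w = levels.shape
    r = spec.window // 2
    valid = g.valid

    out = np.full((h, w), np.nan)
    out_valid = np.zeros((h, w), dtype=bool)
    for row in range(r, h - r):
        for col in range(r, w - r):
            patch = levels[row - r:row + r + 1, col - r:col + r + 1]
            if not valid[row - r:row + r + 1, col - r:col + r + 1].all():
                continue
            gm = GrayImage(levels=patch, ng=spec.ng)
            counts = compute_family_matrix(gm, spec.family)
            out[row, col] = single_feature_from_matrix(
                counts, spec.family, spec.feature, gm.n_valid)
            out_valid[row, col] = True
    if not out_valid.any():
        raise ValueError("ROI too small for TOT")
    return ParametricMap(parameter_id=spec.feature_id, values=out,
                         validity_mask=out_valid,
                         pixel_spacing=qus_map.pixel_spacing,
                         units="arb")


def extract_tot_features(tot_map: ParametricMap, ng: int = 16) -> dict[str, float]:
    """First-order + full texture catalog of one TOT map (85 features)."""
    return map_texture_features(tot_map, ng=ng, include_first_order=True)


def tot_frame_features(maps: dict[str, ParametricMap],
                       specs: list[TOTMapSpec], ng: int = 16) -> dict[str, float]:
    """All TOT features of one frame for the given generating specs."""
    out: dict[str, float] = {}
    for spec in specs:
        if spec.source_parameter not in maps:
            raise KeyError(f"frame has no map {spec.source_parameter!r}")
        tot_map = build_tot_map(maps[spec.source_parameter], spec)
        feats = extract_tot_features(tot_map, ng=ng)
        for key, value in feats.items():
            if key in out:
                raise ValueError(f"duplicate TOT feature name {key!r}")
            out[key] = value
    return out


def assemble_tot_dataset(base5: list[str], stage1: CohortDataset,
                         frames: list[FrameRecord], ng: int = 16,
                         specs: list[TOTMapSpec] | None = None) -> CohortDataset:
    """Enhanced dataset: the 5 generating features + all TOT features.

    Base-feature columns are copied unchanged from the stage-1 dataset;
    TOT features are frame-averaged per patient.  Frames whose TOT maps
    cannot be built are dropped from that patient's average.
    """
    for name in base5:
        if name not in stage1.features.columns:
            raise KeyError(f"base feature {name!r} not in stage-1 dataset")
    specs = specs if specs is not None else [parse_feature_id(n) for n in base5]

    per_patient: dict[str, list[dict[str, float]]] = {}
    for rec in frames:
        try:
            feats = tot_frame_features(rec.maps, specs, ng=ng)
        except ValueError as exc:
            log.warning("TOT failed for %s/%d: %s", rec.patient_id,
                        rec.frame_index, exc)
            continue
        per_patient.setdefault(rec.patient_id, []).append(feats)

    rows = {}
    for patient in stage1.features.index:
        vecs = per_patient.get(patient, [])
        if not vecs:
            log.warning("patient %s has no TOT frames; excluded", patient)
            continue
        keys = vecs[0].keys()
        rows[patient] = {k: float(np.mean([v[k] for v in vecs])) for k in keys}
    # explicit construction: from_dict drops the index when the inner
    # dicts are empty (ablation mode with no TOT specs)
    tot_df = pd.DataFrame(list(rows.values()), index=list(rows.keys())).sort_index()

    base_df = stage1.features.loc[tot_df.index, base5]
    overlap = set(base_df.columns) & set(tot_df.columns)
    if overlap:
        raise ValueError(f"duplicate feature names: {sorted(overlap)}")
    features = pd.concat([base_df, tot_df], axis=1)
    labels = stage1.labels.loc[features.index]
    prov = dict(stage1.provenance)
    prov.update({"stage": "tot", "base5": list(base5)})
    return CohortDataset(features, labels, provenance=prov)
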
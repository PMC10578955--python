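"""Assembly of the patient x feature cohort dataset."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qustex.core import FrameRecord, ParametricMap
from qustex.texture.discretize import discretize
from qustex.texture.features import compute_texture_features
from qustex.texture.firstorder import first_order_features
from qustex.texture.matrices import compute_matrices

log = logging.getLogger(__name__)


@dataclass
class CohortDataset:
    """Patient rows x feature columns with binary outcome labels."""

    features: pd.DataFrame          # index = patient_id
    labels: pd.Series               # "CR" / "PR", same index
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels indices differ")
        if self.features.isna().any().any():
            raise ValueError("NaN cells in assembled dataset")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.provenance, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def subset(self, columns: list[str]) -> "CohortDataset":
        return CohortDataset(self.features[columns].copy(), self.labels.copy(),
                             dict(self.provenance))


def map_texture_features(pmap: ParametricMap, ng: int = 16,
                         include_first_order: bool = False) -> dict[str, float]:
    """68 texture features (optionally + 17 first-order) for one map."""
    g = discretize(pmap.values, ng=ng, valid=pmap.validity_mask,
                   provenance={"parameter_id": pmap.parameter_id})
    out = compute_texture_features(compute_matrices(g),
                                   prefix=f"{pmap.parameter_id}_")
    if include_first_order:
        out.update(first_order_features(pmap.valid_values, ng=ng,
                                        prefix=f"{pmap.parameter_id}_"))
    return out


def frame_feature_vector(maps: dict[str, ParametricMap], ng: int = 16) -> dict[str, float]:
    """Texture features of every map of one frame (7 maps -> 476 features)."""
    out: dict[str, float] = {}
    for pid in sorted(maps):
        out.update(map_texture_features(maps[pid], ng=ng))
    return out


def assemble_dataset(frames: list[FrameRecord], ng: int = 16) -> CohortDataset:
    """Average per-frame feature vectors into one row per patient.

    Frames whose features cannot be computed are dropped; a patient with
    zero usable frames is excluded with a warning.
    """
    per_patient: dict[str, list[dict[str, float]]] = {}
    labels: dict[str, str] = {}
    for rec in frames:
        try:
            feats = frame_feature_vector(rec.maps, ng=ng)
        except ValueError as exc:
            log.warning("frame %s/%d dropped: %s", rec.patient_id,
                        rec.frame_index, exc)
            continue
        per_patient.setdefault(rec.patient_id, []).append(feats)
        labels[rec.patient_id] = rec.label

    rows = {}
    for patient, vecs in per_patient.items():
        if not vecs:
            log.warning("patient %s excluded: no valid frames", patient)
            continue
        keys = vecs[0].keys()
        rows[patient] = {k: float(np.mean([v[k] for v in vecs])) for k in keys}
    if not rows:
        raise ValueError("no patients with valid features")
    features = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    label_s = pd.Series({p: labels[p] for p in features.index}, name="label")
    return CohortDataset(features, label_s, provenance={"ng": ng})
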
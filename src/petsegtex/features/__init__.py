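"""Texture feature extraction: the 83-feature panel over a VOI.

``extract_all`` composes the four families — 20 first-order, 22 GLCM,
35 higher-order (GLRLM/GLSZM/NGTDM) and 6 fractal — after 64-bin
quantization, and guarantees the count contract on every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grids import PETVolume, VOIMask
from .first_order import first_order_features
from .fractal import fractal_features
from .glcm import glcm_features
from .higher_order import higher_order_features
from .quantize import QuantizedVOI, quantize
from .registry import (
    ALL_FEATURES,
    FAMILIES,
    FAMILY_OF,
    FAMILY_SIZES,
    SCREEN_FEATURES,
)

__all__ = [
    "FeatureVector",
    "extract_all",
    "quantize",
    "QuantizedVOI",
    "feature_table",
    "table_to_long",
    "ALL_FEATURES",
    "FAMILIES",
    "FAMILY_OF",
    "FAMILY_SIZES",
    "SCREEN_FEATURES",
    "first_order_features",
    "glcm_features",
    "higher_order_features",
    "fractal_features",
]


@dataclass
class FeatureVector:
    """The 83 named texture values for one (patient, reader, algorithm)."""

    values: dict[str, float]
    patient_id: str = ""
    reader_id: str = ""
    algorithm: str = ""

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != ALL_FEATURES:
            raise ValueError("feature vector does not match the frozen registry")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        meta = {
            "patient_id": self.patient_id,
            "reader_id": self.reader_id,
            "algorithm": self.algorithm,
        }
        return pd.Series({**meta, **self.values})


def extract_all(
    volume: PETVolume,
    mask: VOIMask,
    n_bins: int = 64,
    patient_id: str = "",
    reader_id: str = "",
    algorithm: str = "",
) -> FeatureVector:
    """Extract the full 83-feature panel from one VOI.

    Degenerate inputs (constant VOI, masks too small for a family)
    propagate as NaN in the affected family; no column is ever dropped.
    """
    if mask.is_empty:
        raise ValueError("mask is empty")
    q = quantize(volume, mask, n_bins)
    vals: dict[str, float] = {}
    vals.update(first_order_features(volume, mask, q))
    if mask.n_voxels >= 2:
        vals.update(glcm_features(q))
    else:
        vals.update({name: np.nan for name in FAMILIES["glcm"]})
    vals.update(higher_order_features(q))
    vals.update(fractal_features(volume, mask))
    ordered = {name: float(vals[name]) for name in ALL_FEATURES}
    assert len(ordered) == 83
    for fam, size in FAMILY_SIZES.items():
        assert sum(FAMILY_OF[k] == fam for k in ordered) == size
    return FeatureVector(ordered, patient_id, reader_id, algorithm)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Assemble FeatureVectors into a wide table, one row per key."""
    df = pd.DataFrame([v.to_series() for v in vectors])
    keys = df[["patient_id", "reader_id", "algorithm"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (patient, reader, algorithm) keys")
    return df


def table_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Wide table -> long (patient, reader, algorithm, feature, family, value)."""
    long = table.melt(
        id_vars=["patient_id", "reader_id", "algorithm"],
        var_name="feature",
        value_name="value",
    )
    long["family"] = long["feature"].map(FAMILY_OF)
    return long[
        ["patient_id", "reader_id", "algorithm", "feature", "family", "value"]
    ]
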
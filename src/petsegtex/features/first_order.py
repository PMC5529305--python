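"""First-order (histogram) features: 20 values.

SUV-scale statistics are computed on the raw in-mask intensities;
entropy and uniformity on the 64-level quantized histogram. MATV is the
physical VOI volume in ml and TLG = SUV_mean x MATV.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from ..grids import PETVolume, VOIMask
from .quantize import QuantizedVOI
from .registry import FIRST_ORDER

__all__ = ["first_order_features"]


def first_order_features(
    volume: PETVolume, mask: VOIMask, q: QuantizedVOI
) -> dict[str, float]:
    if mask.is_empty:
        raise ValueError("mask is empty")
    x = volume.values[mask.mask].astype(float)
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=0)
    p = q.probabilities()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    matv = mask.volume_ml
    out = {
        "suv_min": float(x.min()),
        "suv_max": float(x.max()),
        "suv_mean": float(mean),
        "suv_median": float(np.median(x)),
        "suv_sd": float(sd),
        "suv_variance": float(sd**2),
        "fo_skewness": float(sstats.skew(x)) if sd > 0 else 0.0,
        "fo_kurtosis": float(sstats.kurtosis(x)) if sd > 0 else 0.0,
        "fo_energy": float((x**2).sum()),
        "fo_entropy": entropy,
        "fo_uniformity": float((p**2).sum()),
        "suv_range": float(x.max() - x.min()),
        "fo_mad": float(np.abs(x - mean).mean()),
        "fo_rms": float(np.sqrt((x**2).mean())),
        "suv_p10": float(np.percentile(x, 10)),
        "suv_p90": float(np.percentile(x, 90)),
        "suv_iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "fo_cov": float(sd / mean) if mean > 0 else np.nan,
        "matv": float(matv),
        "tlg": float(mean * matv),
    }
    assert tuple(out.keys()) == FIRST_ORDER
    return out
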
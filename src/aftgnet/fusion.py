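"""Cross-weighted fusion of the HOG and TDA descriptors.

Both descriptors are unit-normalized, their cosine similarity alpha is
measured on a shared length basis (leading min(n, m) entries), and the fused
vector is the concatenation [alpha * f_hog || (1 - alpha) * f_tda], truncated
to 2,560 entries so it segments evenly into 8 attention tokens of 320.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HOG_DIM = 1764
TDA_DIM = 800
CONCAT_DIM = HOG_DIM + TDA_DIM  # 2564
FUSED_DIM = 2560

#: alpha used when either descriptor is identically zero (equal weighting)
ZERO_ALPHA = 0.5


@dataclass
class FusedFeatureVector:
    values: np.ndarray  # length 2560
    alpha: float
    source: str = "FUSED"


def unit_normalize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale to unit Euclidean norm; a zero vector is returned as-is with a
    flag so the caller can fall back to equal weighting."""
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return v.copy(), True
    return v / norm, False


def cosine_alpha(f_hog: np.ndarray, f_tda: np.ndarray) -> float:
    """Cosine similarity of the unit-normalized descriptors on their leading
    min-length entries, clamped to [0, 1]; 0.5 if either vector is zero."""
    f_hog = np.asarray(f_hog, dtype=np.float64)
    f_tda = np.asarray(f_tda, dtype=np.float64)
    if f_hog.size == 0 or f_tda.size == 0:
        raise ValueError("cosine_alpha needs two nonempty vectors")
    nh, zero_h = unit_normalize(f_hog)
    nt, zero_t = unit_normalize(f_tda)
    if zero_h or zero_t:
        return ZERO_ALPHA
    m = min(nh.size, nt.size)
    a, b = nh[:m], nt[:m]
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0.0:
        return ZERO_ALPHA
    return float(np.clip(np.dot(a, b) / denom, 0.0, 1.0))


def cross_weighted_fuse(f_hog: np.ndarray, f_tda: np.ndarray) -> FusedFeatureVector:
    """[alpha * unit(f_hog) || (1 - alpha) * unit(f_tda)] truncated to 2,560.

    The pre-truncation concatenation has 1,764 + 800 = 2,564 entries; the
    trailing four are dropped for dimensional consistency with the
    8-token x 320 classifier input.
    """
    f_hog = np.asarray(f_hog, dtype=np.float64)
    f_tda = np.asarray(f_tda, dtype=np.float64)
    if f_hog.size != HOG_DIM:
        raise ValueError(f"HOG vector must have {HOG_DIM} entries, got {f_hog.size}")
    if f_tda.size != TDA_DIM:
        raise ValueError(f"TDA vector must have {TDA_DIM} entries, got {f_tda.size}")
    alpha = cosine_alpha(f_hog, f_tda)
    nh, _ = unit_normalize(f_hog)
    nt, _ = unit_normalize(f_tda)
    fused = np.concatenate([alpha * nh, (1.0 - alpha) * nt])
    assert fused.size == CONCAT_DIM
    return FusedFeatureVector(values=fused[:FUSED_DIM], alpha=alpha)
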
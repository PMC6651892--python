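"""Distance metrics, score normalization, and fusion rules.

Matching works in *dissimilarity* space throughout: a genuine comparison
should give a small score, and a probe is accepted when its best (minimum)
distance to the claimed identity's gallery falls below the decision
threshold. Supported metrics: Euclidean, Manhattan, Spearman distance
(1 − Spearman rank correlation, midranks for ties, range [0, 2]) and
Hamming (fraction of differing coordinates).

Fusion happens either at the feature level — per-modality min-max scaling
with training statistics, then concatenation — or at the score level, where
per-modality distances are min-max normalized to [0, 1] over the current
evaluation run and combined by the sum, min, or product rule.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import rankdata

from .errors import (
    DegenerateNormalizationError,
    DimensionError,
    IntegrityError,
    UndefinedCorrelationError,
)

METRICS = ("euclidean", "manhattan", "spearman", "hamming")
SCORE_RULES = ("sum", "min", "mult")
FUSION_RULES = SCORE_RULES + ("concat",)


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _rank_rows(X: np.ndarray) -> np.ndarray:
    """Midrank transform of each row; rows with zero rank variance are invalid."""
    R = rankdata(X, axis=1)
    if np.any(np.ptp(R, axis=1) == 0):
        raise UndefinedCorrelationError(
            "spearman distance undefined for a constant vector (zero rank variance)"
        )
    return R - R.mean(axis=1, keepdims=True)


def distance(u: Sequence[float], v: Sequence[float], metric: str = "euclidean") -> float:
    """Dissimilarity between two equal-length feature vectors."""
    _check_metric(metric)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise DimensionError(f"shape mismatch: {u.shape} vs {v.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "manhattan":
        return float(np.abs(u - v).sum())
    if metric == "hamming":
        return float(np.mean(u != v))
    # spearman
    if u.size < 2:
        raise DimensionError("spearman distance needs dimension >= 2")
    ru, rv = _rank_rows(np.vstack([u, v]))
    rho = float(ru @ rv / (np.linalg.norm(ru) * np.linalg.norm(rv)))
    return 1.0 - rho


def pairwise_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Condensed distance vector over all unordered row pairs (like pdist)."""
    _check_metric(metric)
    X = np.asarray(X, dtype=float)
    if metric == "euclidean":
        return pdist(X)
    if metric == "manhattan":
        return pdist(X, "cityblock")
    if metric == "hamming":
        return pdist(X, "hamming")
    return pdist(_rank_rows(X), "correlation")


def cross_distances(X: np.ndarray, Y: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Full (n, m) distance matrix between the rows of X and Y."""
    _check_metric(metric)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise DimensionError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if metric == "euclidean":
        return cdist(X, Y)
    if metric == "manhattan":
        return cdist(X, Y, "cityblock")
    if metric == "hamming":
        return cdist(X, Y, "hamming")
    return cdist(_rank_rows(X), _rank_rows(Y), "correlation")


def rowwise_distances(X: np.ndarray, Y: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Distance between corresponding rows of X and Y (one score per pair)."""
    _check_metric(metric)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise DimensionError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if metric == "euclidean":
        return np.linalg.norm(X - Y, axis=1)
    if metric == "manhattan":
        return np.abs(X - Y).sum(axis=1)
    if metric == "hamming":
        return np.mean(X != Y, axis=1)
    RX = _rank_rows(X)
    RY = _rank_rows(Y)
    rho = np.einsum("ij,ij->i", RX, RY) / (
        np.linalg.norm(RX, axis=1) * np.linalg.norm(RY, axis=1)
    )
    return 1.0 - rho


# ---------------------------------------------------------------------------
# Normalization and fusion
# ---------------------------------------------------------------------------

def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """Affine map of a score collection onto [0, 1]; order-preserving."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise DegenerateNormalizationError("constant scores cannot be min-max normalized")
    return (scores - lo) / (hi - lo)


def normalize_scores(per_modality: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Min-max normalize each modality's scores over the current run."""
    return {mod: minmax_normalize(s) for mod, s in per_modality.items()}


def fuse_scores(scores: Sequence[float] | np.ndarray, rule: str) -> float | np.ndarray:
    """Combine m >= 2 normalized per-modality scores into one fused score.

    ``scores`` may be a length-m vector (one comparison) or an (m, n) array
    (m modalities, n comparisons), fused along axis 0.
    """
    if rule == "concat":
        raise IntegrityError("concat is a feature-level rule; use fuse_features")
    if rule not in SCORE_RULES:
        raise ValueError(f"unknown score rule {rule!r}; choose from {SCORE_RULES}")
    arr = np.asarray(scores, dtype=float)
    if arr.shape[0] < 2:
        raise IntegrityError("score fusion needs at least two modalities")
    if rule == "sum":
        out = arr.sum(axis=0)
    elif rule == "min":
        out = arr.min(axis=0)
    else:
        out = arr.prod(axis=0)
    return float(out) if np.ndim(out) == 0 else out


def feature_scaler(train_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (min, max) over a training-session feature matrix."""
    X = np.asarray(train_matrix, dtype=float)
    return X.min(axis=0), X.max(axis=0)


def scale_features(X: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Min-max scale feature columns with training statistics.

    Constant training dimensions carry no ranking information and are mapped
    to 0 to avoid division by zero.
    """
    lo, hi = scaler
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    out = (np.asarray(X, dtype=float) - lo) / safe
    out[:, span == 0] = 0.0
    return out


def fuse_features(
    vectors: Mapping[str, np.ndarray],
    order: Sequence[str],
    scalers: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Concatenate per-modality vectors (or row-matrices) in declared order.

    Each modality is min-max scaled with its training statistics first, so
    no modality dominates the concatenated distance purely by scale.
    """
    missing = [m for m in order if m not in vectors]
    if missing:
        raise IntegrityError(f"missing modality vectors for {missing}")
    parts = []
    for mod in order:
        v = np.atleast_2d(np.asarray(vectors[mod], dtype=float))
        if scalers is not None:
            v = scale_features(v, scalers[mod])
        parts.append(v)
    out = np.hstack(parts)
    return out[0] if all(np.asarray(vectors[m]).ndim == 1 for m in order) else out


def verify(
    probe: np.ndarray,
    gallery: np.ndarray,
    threshold: float,
    metric: str = "euclidean",
) -> bool:
    """Open-set verification decision for a claimed identity.

    Returns True (genuine, w1) iff the minimum distance from the probe to
    the claimed identity's gallery is strictly below the threshold;
    otherwise False (impostor, w2).
    """
    gallery = np.atleast_2d(np.asarray(gallery, dtype=float))
    if gallery.shape[0] == 0:
        raise IntegrityError("empty gallery for claimed identity")
    probe = np.asarray(probe, dtype=float)
    best = cross_distances(probe[None, :], gallery, metric).min()
    return bool(best < threshold)
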
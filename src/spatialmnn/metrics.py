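"""Evaluation metrics: ARI, NMI, and landmark co-localization.

ARI and NMI compare a predicted labelling against a reference at unit
resolution; both are invariant to label renaming. The co-localization index
scores each domain by the mean number of spatial landmarks (e.g. amyloid
plaques) lying strictly within a radius of each of its units.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = ["ari", "nmi", "colocalization_index"]


def _check_pair(labels_a, labels_b):
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"label vectors must be equal-length 1D, got {a.shape} and {b.shape}")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index: 1 = perfect agreement, ~0 = random labelling."""
    a, b = _check_pair(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information in [0, 1].

    Normalized by the arithmetic mean of the two entropies by default
    (other scikit-learn normalizations can be selected).
    """
    a, b = _check_pair(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b,
                                              average_method=average_method))


def colocalization_index(coords, labels, landmarks, radius: float = 20.0):
    """Per-domain mean count of landmarks strictly within ``radius``.

    For each unit the landmarks at Euclidean distance < radius are counted;
    a domain's index is the mean count over its units. Coordinates and
    landmarks must share length units (default radius 20 assumes
    micrometres). Returns {domain: index}; empty domains are absent.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if len(coords) != len(labels):
        raise ValueError("coords and labels length mismatch")
    landmarks = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    if len(landmarks) == 0:
        counts = np.zeros(len(coords))
    else:
        tree = cKDTree(landmarks)
        # query_ball_point includes the boundary; enforce strict inequality
        counts = np.array([
            sum(1 for j in tree.query_ball_point(p, radius)
                if np.linalg.norm(landmarks[j] - p) < radius)
            for p in coords
        ], dtype=float)
    return {dom: float(counts[labels == dom].mean())
            for dom in np.unique(labels)}
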
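"""Evaluation helpers for latent-trajectory recovery."""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import directed_hausdorff


def procrustes_correlation(recovered: np.ndarray, truth: np.ndarray) -> float:
    """Correlation between two point paths after Procrustes alignment.

    Both paths are centred and scaled to unit Frobenius norm, the optimal
    orthogonal map from ``recovered`` onto ``truth`` is applied, and the
    Pearson correlation of the flattened aligned coordinates is returned.
    Invariant to rotation, reflection, translation and global scale of
    either path; 1.0 means the shapes coincide.
    """
    A = np.asarray(recovered, dtype=float)
    B = np.asarray(truth, dtype=float)
    if A.shape != B.shape:
        raise ValueError("paths must share a shape")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A /= np.linalg.norm(A)
    B /= np.linalg.norm(B)
    R, _ = orthogonal_procrustes(A, B)
    a, b = (A @ R).ravel(), B.ravel()
    return float(np.corrcoef(a, b)[0, 1])


def hausdorff_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    return max(directed_hausdorff(A, B)[0], directed_hausdorff(B, A)[0])
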
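"""Shape PCA and group mean shapes.

Covariance PCA of mean-centred, flattened (x1, y1, z1, ..., xk, yk, zk)
superimposed coordinates. Axis signs follow a fixed convention (largest
magnitude loading positive) so scores are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superimposition import AlignedShapes


class OrdinationError(ValueError):
    pass


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, m)
    axes: np.ndarray  # (m, 3k) orthonormal rows
    var_prop: np.ndarray  # (m,)
    eigenvalues: np.ndarray  # (m,)
    total_variance: float
    center: np.ndarray  # (3k,) mean of the training data

    @property
    def m(self) -> int:
        return self.axes.shape[0]


def _flat(shapes) -> np.ndarray:
    if isinstance(shapes, AlignedShapes):
        return shapes.flat()
    arr = np.asarray(shapes, dtype=float)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1)
    if arr.ndim == 2 and arr.shape[1] == 3:
        return arr.reshape(1, -1)
    return np.atleast_2d(arr)


def shape_pca(aligned) -> PcaResult:
    """Covariance PCA of superimposed shape coordinates."""
    x = _flat(aligned)
    n, p = x.shape
    if n < 3:
        raise OrdinationError(f"PCA needs at least 3 specimens, got {n}")
    center = x.mean(axis=0)
    xc = x - center
    # SVD route: eigenvalues of the covariance are s^2 / (n - 1)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    m = min(n - 1, p)
    eigenvalues = (s[:m] ** 2) / (n - 1)
    axes = vt[:m]
    # deterministic sign: largest-magnitude loading of each axis positive
    idx = np.argmax(np.abs(axes), axis=1)
    signs = np.sign(axes[np.arange(m), idx])
    signs[signs == 0] = 1.0
    axes = axes * signs[:, None]
    scores = xc @ axes.T
    total = float(xc.var(axis=0, ddof=1).sum())
    var_prop = eigenvalues / total if total > 0 else np.zeros(m)
    return PcaResult(
        scores=scores,
        axes=axes,
        var_prop=var_prop,
        eigenvalues=eigenvalues,
        total_variance=total,
        center=center,
    )


def group_mean_shapes(aligned, labels) -> dict:
    """Coordinate-wise mean shape (k, 3) per factor level."""
    coords = aligned.coords if isinstance(aligned, AlignedShapes) else np.asarray(aligned, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != coords.shape[0]:
        raise OrdinationError("labels length does not match number of shapes")
    means = {}
    for level in dict.fromkeys(labels):  # preserves first-appearance order
        mask = labels == level
        if not mask.any():
            raise OrdinationError(f"empty group {level!r}")
        means[level] = coords[mask].mean(axis=0)
    return means


def project(shapes, pca: PcaResult) -> np.ndarray:
    """Project shapes (aligned in the same superimposition) onto PCA axes."""
    x = _flat(shapes)
    if x.shape[1] != pca.center.shape[0]:
        raise OrdinationError(
            f"coordinate dimension {x.shape[1]} does not match PCA "
            f"training dimension {pca.center.shape[0]}"
        )
    return (x - pca.center) @ pca.axes.T
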
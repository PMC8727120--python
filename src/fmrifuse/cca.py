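"""Canonical correlation analysis for fusing two per-subject feature sets.

Given paired feature matrices X (m x n2) and Y (m x n3) — here the PCANet
features of the mALFF and mReHo maps of the same subjects — CCA finds
projection pairs (a, b) maximizing corr(Xa, Yb), subject to successive pairs
being uncorrelated. The fused representation is the concatenation (or sum)
of the two projected views.

PCANet features have far more columns than there are subjects, so plain CCA
is singular. Two standard stabilizers are applied: an optional per-view PCA
pre-reduction (default to min(m - 2, 64) components) and a ridge term added
to each view's covariance diagonal. The canonical system is solved by
whitened SVD: with Cxx, Cyy the (ridged) within-view covariances and Cxy the
cross-covariance, the singular values of Cxx^(-1/2) Cxy Cyy^(-1/2) are the
canonical correlations and the transformed singular vectors the projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["CCAModel", "fit_cca", "transform_fuse"]


@dataclass(frozen=True)
class CCAModel:
    """Fitted projections, training canonical correlations and the per-view
    centering/scaling (and optional PCA bases) needed to transform new data."""

    proj_x: np.ndarray  # (n2_reduced, n_components)
    proj_y: np.ndarray  # (n3_reduced, n_components)
    correlations: np.ndarray  # (n_components,), non-increasing, in [0, 1]
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    x_pca: np.ndarray | None = None  # (n2, n2_reduced) orthonormal basis
    y_pca: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.correlations)


def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = a.mean(axis=0)
    scale = a.std(axis=0, ddof=1)
    zero_var = scale == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); left unscaled",
            stacklevel=3,
        )
        scale = np.where(zero_var, 1.0, scale)
    return (a - center) / scale, center, scale


def _pca_basis(a: np.ndarray, max_dim: int) -> np.ndarray | None:
    """Orthonormal principal basis when the view is wider than ``max_dim``."""
    if a.shape[1] <= max_dim:
        return None
    # right singular vectors of the centered/standardized view
    _, _, vt = np.linalg.svd(a, full_matrices=False)
    return vt[:max_dim].T


def _inv_sqrt(c: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = linalg.eigh(c)
    eigvals = np.maximum(eigvals, 1e-14 * eigvals.max())
    return eigvecs @ np.diag(eigvals**-0.5) @ eigvecs.T


def fit_cca(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    ridge: float = 1e-3,
    pca_dim: int | None = None,
) -> CCAModel:
    """Fit regularized CCA on paired rows of ``x`` (m x n2) and ``y`` (m x n3).

    Parameters
    ----------
    n_components
        Number of canonical pairs; must not exceed min(n2, n3, m - 1) after
        any PCA pre-reduction. ``None`` uses min(10, that bound).
    ridge
        Non-negative term added to each view's covariance diagonal (scaled by
        the mean diagonal), stabilizing the p >> m regime. 0 recovers plain CCA.
    pca_dim
        Per-view PCA pre-reduction width; ``None`` uses min(m - 2, 64), and a
        view narrower than the limit is left unreduced.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError(f"paired 2D matrices required, got {x.shape} and {y.shape}")
    m = x.shape[0]
    if m < 3:
        raise ValueError(f"need at least 3 paired samples, got {m}")
    if ridge < 0:
        raise ValueError(f"ridge must be non-negative, got {ridge}")

    xs, x_center, x_scale = _standardize(x)
    ys, y_center, y_scale = _standardize(y)
    if pca_dim is None:
        pca_dim = min(m - 2, 64)
    x_basis = _pca_basis(xs, pca_dim)
    y_basis = _pca_basis(ys, pca_dim)
    xr = xs @ x_basis if x_basis is not None else xs
    yr = ys @ y_basis if y_basis is not None else ys

    max_components = min(xr.shape[1], yr.shape[1], m - 1)
    if n_components is None:
        n_components = min(10, max_components)
    if n_components > max_components:
        raise ValueError(
            f"n_components={n_components} exceeds the attainable {max_components}"
        )

    cxx = xr.T @ xr / (m - 1)
    cyy = yr.T @ yr / (m - 1)
    cxy = xr.T @ yr / (m - 1)
    if ridge > 0:
        cxx = cxx + ridge * np.mean(np.diag(cxx)) * np.eye(cxx.shape[0])
        cyy = cyy + ridge * np.mean(np.diag(cyy)) * np.eye(cyy.shape[0])
    wx = _inv_sqrt(cxx)
    wy = _inv_sqrt(cyy)
    u, s, vt = np.linalg.svd(wx @ cxy @ wy)
    s = np.clip(s[:n_components], 0.0, 1.0)
    proj_x = wx @ u[:, :n_components]
    proj_y = wy @ vt[:n_components].T
    return CCAModel(
        proj_x=proj_x,
        proj_y=proj_y,
        correlations=s,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        x_pca=x_basis,
        y_pca=y_basis,
    )


def _project(a: np.ndarray, center: np.ndarray, scale: np.ndarray,
             basis: np.ndarray | None, proj: np.ndarray) -> np.ndarray:
    z = (a - center) / scale
    if basis is not None:
        z = z @ basis
    return z @ proj


def transform_fuse(
    model: CCAModel, x: np.ndarray, y: np.ndarray, mode: str = "concat"
) -> np.ndarray:
    """Project both views with the fitted model and fuse them.

    ``concat`` returns [X' | Y'] (m x 2n'); ``sum`` returns X' + Y' (m x n').
    Only stored centering, scaling, PCA bases and projections are used, so
    held-out subjects never influence the fit.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[1] != len(model.x_center) or y.shape[1] != len(model.y_center):
        raise ValueError(
            f"column counts ({x.shape[1]}, {y.shape[1]}) do not match the fit "
            f"({len(model.x_center)}, {len(model.y_center)})"
        )
    xp = _project(x, model.x_center, model.x_scale, model.x_pca, model.proj_x)
    yp = _project(y, model.y_center, model.y_scale, model.y_pca, model.proj_y)
    if mode == "concat":
        return np.hstack([xp, yp])
    if mode == "sum":
        return xp + yp
    raise ValueError(f"mode must be 'concat' or 'sum', got {mode!r}")
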
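"""Regional homogeneity (ReHo): Kendall's coefficient of concordance W of a
voxel's time series with its 6/18/26 nearest neighbors, and the whole-brain
normalized mReHo map.

For a voxel with K neighbors, the K+1 series of length T are column-ranked
and W is

    W = (sum_i SR_i^2 - T * SRbar^2) / ((1/12) (K+1)^2 (T^3 - T))

where SR_i is the rank sum across the K+1 series at time point i and SRbar
its average (T+1)(K+1)/2. W is 1 when all series share one rank ordering and
0 when rank sums are flat. Ties get average ranks; the classical tie
correction of the denominator is deliberately not applied (BOLD floats
essentially never tie), which can only shrink W.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import rankdata

from .alff import FrequencyBand, bandpass_series
from .volumes import (
    BrainMask,
    Volume3D,
    Volume4D,
    gaussian_smooth,
    normalize_map_by_mask_mean,
)

__all__ = [
    "NeighborhoodScheme",
    "neighborhood_offsets",
    "rank_columns",
    "kendalls_w",
    "reho_map",
    "mreho_map",
]


@dataclass(frozen=True)
class NeighborhoodScheme:
    """The K nearest-neighbor displacement set of a voxel (K in {6, 18, 26})."""

    k_neighbors: int
    offsets: tuple[tuple[int, int, int], ...]


def neighborhood_offsets(k: int) -> NeighborhoodScheme:
    """Offsets for K=6 (faces), 18 (faces+edges) or 26 (full 3x3x3 shell)."""
    if k not in (6, 18, 26):
        raise ValueError(f"k_neighbors must be one of 6, 18, 26; got {k}")
    all_offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    max_l1 = {6: 1, 18: 2, 26: 3}[k]
    offsets = tuple(o for o in all_offsets if sum(map(abs, o)) <= max_l1)
    return NeighborhoodScheme(k_neighbors=k, offsets=offsets)


def rank_columns(x: np.ndarray) -> np.ndarray:
    """Rank each column of a T x (K+1) matrix; smallest value gets rank 1,
    ties the average of the tied ranks."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError(f"need a T x m matrix with T >= 2, got shape {x.shape}")
    return rankdata(x, axis=0, method="average")


def kendalls_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance from a T x (K+1) rank matrix."""
    r = np.asarray(ranks, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError(f"need a 2D rank matrix, got shape {r.shape}")
    t_len, m = r.shape
    if t_len < 2 or m < 2:
        raise ValueError(f"need T >= 2 and at least 2 columns, got {r.shape}")
    row_sums = r.sum(axis=1)
    mean_sum = row_sums.mean()
    numerator = float((row_sums**2).sum() - t_len * mean_sum**2)
    denominator = (m**2) * (t_len**3 - t_len) / 12.0
    w = numerator / denominator
    return max(w, 0.0)  # clamp float noise below zero


def _neighbor_count_and_rank_sums(
    ranks4d: np.ndarray, mask: np.ndarray, offsets: tuple[tuple[int, int, int], ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate, per voxel, the number of in-mask neighborhood members and
    the across-members rank sum at each time point, using shifted views."""
    nx, ny, nz, t_len = ranks4d.shape
    pad_r = np.zeros((nx + 2, ny + 2, nz + 2, t_len))
    pad_r[1:-1, 1:-1, 1:-1, :] = ranks4d * mask[..., None]
    pad_m = np.zeros((nx + 2, ny + 2, nz + 2), dtype=np.int64)
    pad_m[1:-1, 1:-1, 1:-1] = mask
    sums = ranks4d * mask[..., None]
    counts = mask.astype(np.int64).copy()
    for dx, dy, dz in offsets:
        sl = (slice(1 + dx, nx + 1 + dx), slice(1 + dy, ny + 1 + dy), slice(1 + dz, nz + 1 + dz))
        sums = sums + pad_r[sl]
        counts = counts + pad_m[sl]
    return counts, sums


def reho_map(v: Volume4D, mask: BrainMask, scheme: NeighborhoodScheme) -> Volume3D:
    """Voxelwise Kendall's W over each voxel's (K+1)-series neighborhood.

    A voxel gets a value only when its entire neighborhood lies inside both
    the volume and the mask; boundary/partial-neighborhood voxels are 0 so
    the (K+1) factor in W's denominator stays exact.
    """
    if v.spatial_shape != mask.data.shape:
        raise ValueError(f"volume {v.spatial_shape} and mask {mask.data.shape} disagree")
    t_len = v.n_frames
    m = scheme.k_neighbors + 1
    ranks = rankdata(v.data, axis=3, method="average")
    counts, rank_sums = _neighbor_count_and_rank_sums(ranks, mask.data, scheme.offsets)
    valid = mask.data & (counts == m)
    sr = rank_sums[valid]  # (n_valid, T)
    mean_sr = sr.mean(axis=1)
    numerator = (sr**2).sum(axis=1) - t_len * mean_sr**2
    denominator = (m**2) * (t_len**3 - t_len) / 12.0
    out = np.zeros(v.spatial_shape)
    out[valid] = np.maximum(numerator / denominator, 0.0)
    return Volume3D(data=out, spacing_mm=v.spacing_mm)


def mreho_map(
    v: Volume4D,
    mask: BrainMask,
    scheme: NeighborhoodScheme,
    band: FrequencyBand | None = None,
    fwhm_mm: float = 4.0,
) -> Volume3D:
    """mReHo: optional band-limiting, ReHo, whole-brain normalization, smoothing.

    The in-mask mean equals 1 before the smoothing step. ``band=None`` ranks
    the raw series; a band applies an ideal FFT-mask filter first (the
    0.01-0.08 Hz and 0.01-0.04 Hz variants).
    """
    if band is not None:
        filtered = bandpass_series(v.data, v.tr_seconds, band)
        v = Volume4D(data=filtered, tr_seconds=v.tr_seconds, spacing_mm=v.spacing_mm)
    raw = reho_map(v, mask, scheme)
    normalized = normalize_map_by_mask_mean(raw, mask)
    return gaussian_smooth(normalized, fwhm_mm)
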
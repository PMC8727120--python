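"""3D PCANet with max-pooling and ReLU after every convolution stage.

PCANet is a convolution network whose kernels are not trained by
backpropagation: each stage's filter bank is the set of leading eigenvectors
of the covariance (scatter) of mean-removed k*k*k patches pooled over all
training images. This variant inserts a max-pooling window and a ReLU after
each of the two convolution stages, which shrinks the maps and discards
negative responses before the binary encoding. The forward pass is:

  stage 1: convolve each input map with the C1 stage-1 kernels, pool+ReLU
  stage 2: convolve each stage-1 output with the C2 stage-2 kernels, pool+ReLU
  encode:  per (input, stage-1 filter), combine the C2 stage-2 outputs into
           one integer map, O = sum_h 2^(h-1) * H(Omega_h), H(x)=1 iff x>0
  feature: overlapping block histograms of the encoded maps (2^C2 bins per
           block), concatenated over blocks and stage-1 filters; final
           length C1 * beta * 2^C2.

Filter learning is deterministic: the eigendecomposition is done on the
small k^3 x k^3 scatter matrix and each eigenvector's sign is fixed so its
largest-magnitude component is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import Volume3D

__all__ = [
    "PCANetParams",
    "FilterBank",
    "PCANet3D",
    "extract_patches",
    "learn_filters",
    "convolve3d",
    "pool_relu",
    "stage_forward",
    "heaviside_encode",
    "block_histograms",
]


@dataclass(frozen=True)
class PCANetParams:
    """Hyperparameters of the two-stage network.

    k: odd kernel/patch edge; c1, c2: filters per stage; pool/pool_stride:
    max-pool window and stride; overlap_r: histogram-block overlap rate R in
    [0, 1); beta: number of histogram blocks used per encoded map;
    hist_block: histogram block edge (defaults to k); patch_stride: patch
    sampling stride during filter learning.
    """

    k: int = 3
    c1: int = 4
    c2: int = 4
    pool: int = 2
    pool_stride: int = 2
    overlap_r: float = 0.0
    beta: int = 8
    hist_block: int | None = None
    patch_stride: int = 1

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 1, got {self.k}")
        if not (1 <= self.c1 <= self.k**3 and 1 <= self.c2 <= self.k**3):
            raise ValueError(f"need 1 <= c1, c2 <= k^3={self.k**3}, got {self.c1}, {self.c2}")
        if not 0 <= self.overlap_r < 1:
            raise ValueError(f"overlap_r must be in [0, 1), got {self.overlap_r}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if self.pool < 1 or self.pool_stride < 1:
            raise ValueError("pool and pool_stride must be >= 1")
        if self.patch_stride < 1:
            raise ValueError("patch_stride must be >= 1")

    @property
    def histogram_block_edge(self) -> int:
        return self.hist_block if self.hist_block is not None else self.k

    @property
    def n_bins(self) -> int:
        return 2**self.c2

    @property
    def feature_length(self) -> int:
        return self.c1 * self.beta * self.n_bins


@dataclass(frozen=True)
class FilterBank:
    """Orthonormal PCA convolution kernels of one stage, eigenvalue-ordered."""

    kernels: np.ndarray  # (C, k, k, k)
    eigenvalues: np.ndarray  # (C,), non-increasing

    def __post_init__(self) -> None:
        if self.kernels.ndim != 4:
            raise ValueError(f"kernels must be (C, k, k, k), got {self.kernels.shape}")
        if len(self.eigenvalues) != len(self.kernels):
            raise ValueError("one eigenvalue per kernel required")

    def __len__(self) -> int:
        return len(self.kernels)


def _as_array(m: Volume3D | np.ndarray) -> np.ndarray:
    return m.data if isinstance(m, Volume3D) else np.asarray(m, dtype=np.float64)


def extract_patches(m: Volume3D | np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """Vectorized, mean-removed k^3 sliding patches as columns.

    "Standardized" means per-patch mean removal only (no variance scaling),
    the original PCANet convention; a constant map therefore yields an
    all-zero patch matrix.
    """
    data = _as_array(m)
    if any(d < k for d in data.shape):
        raise ValueError(f"patch edge k={k} exceeds a volume dim {data.shape}")
    windows = np.lib.stride_tricks.sliding_window_view(data, (k, k, k))
    windows = windows[::stride, ::stride, ::stride]
    cols = windows.reshape(-1, k**3).T.astype(np.float64)  # (k^3, n_patches)
    return cols - cols.mean(axis=0, keepdims=True)


def learn_filters(patches: np.ndarray, c: int, k: int) -> FilterBank:
    """Top-c eigenvectors of the patch scatter U U^T, reshaped to k^3 kernels.

    The decomposition runs on the small k^3 x k^3 scatter, never on the patch
    matrix itself. Sign convention: each kernel's largest-magnitude component
    is made positive, so refits are bitwise reproducible.
    """
    if patches.shape[0] != k**3:
        raise ValueError(f"patch rows {patches.shape[0]} != k^3 = {k**3}")
    if c > k**3:
        raise ValueError(f"cannot learn c={c} filters from k^3={k**3}-dim patches")
    if not np.any(patches):
        raise ValueError("patch matrix is identically zero; filters undefined")
    scatter = patches @ patches.T
    eigvals, eigvecs = np.linalg.eigh(scatter)  # ascending
    order = np.argsort(eigvals)[::-1][:c]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for i in range(c):
        pivot = np.argmax(np.abs(eigvecs[:, i]))
        if eigvecs[pivot, i] < 0:
            eigvecs[:, i] = -eigvecs[:, i]
    kernels = eigvecs.T.reshape(c, k, k, k)
    return FilterBank(kernels=kernels, eigenvalues=np.maximum(eigvals, 0.0))


def convolve3d(m: Volume3D | np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size filtering with zero padding of (k-1)/2 on each side.

    Cross-correlation orientation (the kernel is not flipped); with
    PCA-learned kernels the orientation is a labeling convention only.
    """
    data = _as_array(m)
    kernel = np.asarray(kernel, dtype=np.float64)
    k = kernel.shape[0]
    if kernel.shape != (k, k, k) or k % 2 == 0:
        raise ValueError(f"kernel must be cubic with odd edge, got {kernel.shape}")
    if any(d < k for d in data.shape):
        raise ValueError(f"kernel edge {k} exceeds a volume dim {data.shape}")
    return ndimage.correlate(data, kernel, mode="constant", cval=0.0)


def pool_relu(m: Volume3D | np.ndarray, pool: int, stride: int | None = None) -> np.ndarray:
    """Windowed max over pool^3 blocks at the given stride, then ReLU."""
    data = _as_array(m)
    if stride is None:
        stride = pool
    if pool < 1 or stride < 1:
        raise ValueError("pool and stride must be >= 1")
    if stride > pool:
        warnings.warn(
            f"pool stride {stride} > window {pool}: some voxels are skipped",
            stacklevel=2,
        )
    if any(d < pool for d in data.shape):
        raise ValueError(f"pool window {pool} exceeds a volume dim {data.shape}")
    if pool == 1 and stride == 1:
        return np.maximum(data, 0.0)
    windows = np.lib.stride_tricks.sliding_window_view(data, (pool, pool, pool))
    windows = windows[::stride, ::stride, ::stride]
    pooled = windows.max(axis=(-3, -2, -1))
    return np.maximum(pooled, 0.0)


def stage_forward(
    images: list[np.ndarray] | list[Volume3D],
    bank: FilterBank,
    pool: int,
    pool_stride: int,
) -> list[np.ndarray]:
    """One network stage: every image through every kernel, then pool+ReLU.

    Output order is image-major, filter-minor: outputs of image 0 with
    kernels 0..C-1 come first.
    """
    outputs: list[np.ndarray] = []
    for image in images:
        for kernel in bank.kernels:
            outputs.append(pool_relu(convolve3d(image, kernel), pool, pool_stride))
    return outputs


def heaviside_encode(stage2_outputs: list[np.ndarray]) -> np.ndarray:
    """Binary-encode C2 stage-2 maps into one integer map in [0, 2^C2 - 1].

    Bit h-1 (weight 2^(h-1)) is set where the h-th map is strictly positive;
    H(0) = 0.
    """
    if not stage2_outputs:
        raise ValueError("need at least one stage-2 output")
    shape = stage2_outputs[0].shape
    encoded = np.zeros(shape, dtype=np.int64)
    for h, omega in enumerate(stage2_outputs, start=1):
        if omega.shape != shape:
            raise ValueError(f"shape mismatch: {omega.shape} vs {shape}")
        encoded += (2 ** (h - 1)) * (omega > 0).astype(np.int64)
    return encoded


def _block_starts(dim: int, edge: int, stride: int) -> list[int]:
    return list(range(0, dim - edge + 1, stride))


def block_histograms(encoded: np.ndarray, p: PCANetParams) -> np.ndarray:
    """Per-block count histograms of an encoded map, concatenated.

    Blocks of edge ``hist_block`` tile the map with stride
    ``round(hist_block * (1 - R))`` (R = 0 means non-overlapping); the first
    ``beta`` blocks in lexicographic (x, y, z) start order are used. Each
    block contributes 2^C2 counts summing to hist_block^3.
    """
    edge = p.histogram_block_edge
    if any(d < edge for d in encoded.shape):
        raise ValueError(f"histogram block edge {edge} exceeds map shape {encoded.shape}")
    stride = max(1, round(edge * (1.0 - p.overlap_r)))
    starts = [_block_starts(d, edge, stride) for d in encoded.shape]
    n_blocks = len(starts[0]) * len(starts[1]) * len(starts[2])
    if n_blocks < p.beta:
        raise ValueError(
            f"tiling of {encoded.shape} with edge {edge}, stride {stride} yields only "
            f"{n_blocks} blocks; beta={p.beta} requested (reduce beta or hist_block)"
        )
    histograms = []
    done = 0
    for x0 in starts[0]:
        for y0 in starts[1]:
            for z0 in starts[2]:
                if done == p.beta:
                    break
                block = encoded[x0 : x0 + edge, y0 : y0 + edge, z0 : z0 + edge]
                histograms.append(np.bincount(block.ravel(), minlength=p.n_bins))
                done += 1
    return np.concatenate(histograms).astype(np.float64)


@dataclass
class PCANet3D:
    """Two-stage 3D PCANet feature extractor (fit = learn both filter banks)."""

    params: PCANetParams = field(default_factory=PCANetParams)
    stage1: FilterBank | None = None
    stage2: FilterBank | None = None

    @property
    def is_fitted(self) -> bool:
        return self.stage1 is not None and self.stage2 is not None

    def fit(self, images: list[Volume3D] | list[np.ndarray]) -> "PCANet3D":
        """Learn the stage-1 bank from patches pooled over all training maps,
        run stage 1, and learn the stage-2 bank from the pooled stage-1
        outputs. Deterministic for fixed inputs."""
        if not images:
            raise ValueError("need at least one training image")
        p = self.params
        pooled = np.concatenate(
            [extract_patches(img, p.k, p.patch_stride) for img in images], axis=1
        )
        self.stage1 = learn_filters(pooled, p.c1, p.k)
        stage1_out = stage_forward(images, self.stage1, p.pool, p.pool_stride)
        pooled2 = np.concatenate(
            [extract_patches(img, p.k, p.patch_stride) for img in stage1_out], axis=1
        )
        self.stage2 = learn_filters(pooled2, p.c2, p.k)
        return self

    def transform(self, images: list[Volume3D] | list[np.ndarray]) -> np.ndarray:
        """Feature matrix (n_images, C1 * beta * 2^C2) using the fitted banks.

        Read-only on the model: applying it to held-out maps never refits.
        """
        if not self.is_fitted:
            raise RuntimeError("PCANet3D must be fitted before transform")
        p = self.params
        features = []
        for image in images:
            stage1_out = stage_forward([image], self.stage1, p.pool, p.pool_stride)
            per_filter = []
            for pi in stage1_out:  # one per stage-1 filter l
                stage2_out = stage_forward([pi], self.stage2, p.pool, p.pool_stride)
                encoded = heaviside_encode(stage2_out)
                per_filter.append(block_histograms(encoded, p))
            features.append(np.concatenate(per_filter))
        out = np.asarray(features)
        assert out.shape[1] == p.feature_length
        return out

    def fit_transform(self, images: list[Volume3D] | list[np.ndarray]) -> np.ndarray:
        return self.fit(images).transform(images)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist params + both banks to one .npz archive with a version tag."""
        if not self.is_fitted:
            raise RuntimeError("cannot save an unfitted model")
        meta = {"format_version": 1, "params": self.params.__dict__}
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            stage1_kernels=self.stage1.kernels,
            stage1_eigenvalues=self.stage1.eigenvalues,
            stage2_kernels=self.stage2.kernels,
            stage2_eigenvalues=self.stage2.eigenvalues,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCANet3D":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"]).decode())
            if meta.get("format_version") != 1:
                raise ValueError(f"unsupported model format: {meta.get('format_version')}")
            params = PCANetParams(**meta["params"])
            stage1 = FilterBank(archive["stage1_kernels"], archive["stage1_eigenvalues"])
            stage2 = FilterBank(archive["stage2_kernels"], archive["stage2_eigenvalues"])
        return cls(params=params, stage1=stage1, stage2=stage2)
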
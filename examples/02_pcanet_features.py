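"""Learn 3D PCANet filters from a few maps and extract histogram features.

The filter banks are eigenvectors of pooled patch covariance, so they come
out orthonormal with non-increasing eigenvalues; the feature vector is a
concatenation of block histograms of Heaviside-encoded stage-2 responses.
"""

import numpy as np

from fmrifuse import PCANet3D, PCANetParams

rng = np.random.default_rng(0)
maps = [rng.standard_normal((16, 16, 16)) for _ in range(8)]

params = PCANetParams(k=3, c1=4, c2=4, pool=2, pool_stride=2, beta=8, hist_block=2)
net = PCANet3D(params).fit(maps)
features = net.transform(maps)

flat = net.stage1.kernels.reshape(len(net.stage1), -1)
print("stage-1 kernel gram matrix (should be identity):")
print(np.round(flat @ flat.T, 6))
print("stage-1 eigenvalues:", np.round(net.stage1.eigenvalues, 2))
print(f"feature matrix: {features.shape}  "
      f"(C1*beta*2^C2 = {params.c1}*{params.beta}*{2**params.c2} = {params.feature_length})")
print("per-block histogram sums (= block voxel count,",
      f"{params.histogram_block_edge ** 3}):",
      np.unique(features.reshape(len(maps), -1, params.n_bins).sum(axis=2)))
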
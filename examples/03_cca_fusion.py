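"""Fuse two feature views with canonical correlation analysis.

Simulates the textbook latent model x = z + e, y = z + e' whose population
correlation is 0.5; the first canonical correlation should land close to it.
Then fuses two multivariate views that share a latent factor and shows the
fused columns are maximally correlated pairs.
"""

import numpy as np

from fmrifuse import fit_cca, transform_fuse

rng = np.random.default_rng(0)

# scalar latent model: population canonical correlation = 0.5
m = 2000
z = rng.standard_normal(m)
model = fit_cca((z + rng.standard_normal(m))[:, None],
                (z + rng.standard_normal(m))[:, None],
                n_components=1, ridge=0.0)
print(f"latent-model first canonical correlation: {model.correlations[0]:.3f} "
      "(population value 0.5)")

# multivariate fusion
x = rng.standard_normal((100, 20))
y = x @ rng.standard_normal((20, 15)) + 2.0 * rng.standard_normal((100, 15))
model = fit_cca(x, y, n_components=3)
fused = transform_fuse(model, x, y, mode="concat")
print("canonical correlations:", np.round(model.correlations, 3))
print(f"fused matrix: {fused.shape} (projected x-columns | projected y-columns)")
for i in range(3):
    r = np.corrcoef(fused[:, i], fused[:, 3 + i])[0, 1]
    print(f"  corr(fused x[{i}], fused y[{i}]) = {r:.3f}")
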
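# Methods

This note records the modelling choices, defaults and numerical conventions
behind `fmrifuse`, and what the synthetic validation does and does not show.

## Signal model and maps

The input is a per-subject 4D BOLD array (X, Y, Z, T) with repetition time
TR. The first `drop_initial` frames (default 10) are discarded because the
scanner signal has not reached steady state. A brain mask defines "whole
brain"; when none is supplied, voxels whose temporal mean exceeds 10% of the
robust (98th-percentile) maximum are used — adequate for phantoms and
skull-stripped data, not a substitute for a real brain extraction.

**ALFF.** The series is linearly detrended (least-squares line removal; the
residual is orthogonal to both the constant and the ramp), transformed with
an FFT, and the square root of the periodogram power `|DFT|²/T` is averaged
over bins with `f_low ≤ f ≤ f_high`, excluding DC and Nyquist. A band-edge
bin is included (closed interval). Selecting in-band periodogram bins is
algebraically identical to an ideal FFT-mask bandpass followed by a
full-spectrum RMS, so "filter, then spectrum" is implemented as one step;
the order ambiguity between detrending and filtering is resolved by always
detrending first (for an ideal mask filter the two orders agree except for
the removed trend itself). The periodogram normalization (division by T) is
a convention; mALFF is invariant to it, and the amplitude-linearity and
oracle tests pin the implemented choice.

**ReHo.** Kendall's W over each voxel's (K+1)-series neighborhood, K ∈
{6, 18, 26} (face / face+edge / full shell). Ranks are per-series over time
with average ranks for ties; the classical tie-correction term is *not*
applied — BOLD floats essentially never tie, and omitting the correction
can only shrink W. The denominator uses T³ − T with T the number of time
points. Voxels whose neighborhood leaves the volume or the mask are set to
0 rather than computed on partial neighborhoods, keeping the (K+1)² factor
exact. The production path vectorizes the computation (volume-wide ranking,
shifted-view rank-sum accumulation); a literal-formula implementation lives
in the tests as the independent oracle. An optional ideal-bandpass
(0.01–0.08 Hz by default, 0.01–0.04 Hz as a variant) is applied before
ranking; whether to rank raw or filtered series is exposed as a flag
(`reho_band=None` ranks raw series).

**Normalization and smoothing.** Both maps are divided by their in-mask
mean (in-mask mean exactly 1 afterwards). mReHo is smoothed *after*
normalization with an isotropic Gaussian, FWHM default 4 mm (σ = FWHM /
(2√(2 ln 2))), reflect padding; mALFF is not smoothed by default. Both the
kernel width and the order are configurable because neither is standardized
across toolchains.

## 3D PCANet

Two convolution stages with PCA-learned kernels, each followed by
max-pooling and ReLU. Choices that the architecture leaves open:

- *Patch standardization* is per-patch mean removal only (no variance
  scaling), the original PCANet convention.
- *Eigendecomposition* runs on the k³×k³ patch scatter UUᵀ, never on the
  patch matrix; each eigenvector's sign is fixed (largest-magnitude
  component positive) so refits are bitwise identical.
- *Convolution* is same-size with zero padding of (k−1)/2, cross-correlation
  orientation; even k is rejected. Same-size outputs keep the histogram
  geometry independent of k.
- *Pooling* window and stride default to 2/2 (halving each dimension); a
  stride larger than the window is allowed but warned about.
- *Stage-2 filters* are learned from, and applied to, the pooled+ReLU
  stage-1 outputs.
- *Heaviside encoding* uses H(0) = 0 and bit weight 2^(h−1) for stage-2
  filter h, giving integer maps in [0, 2^C2 − 1].
- *Histograms*: blocks of edge `hist_block` (default k) tile the encoded
  map with stride `round(hist_block·(1−R))`; the first β blocks in
  lexicographic order are counted into 2^C2 bins each. Requesting more
  blocks than the tiling provides is an error that reports the achievable
  count.

Default hyperparameters k=3, C1=C2=4, β=8 sit inside the conventional
search ranges (k 2–8, C1/C2 2–6, R 0–0.6, β 5–25); the pipeline default
uses `hist_block=2` because two pool-by-2 stages reduce a 16³ map to 4³,
which edge-2 blocks tile into exactly 8 non-overlapping blocks. The
grid-search helper restricts k to odd {3, 5, 7} since same-size padding
requires odd kernels.

## CCA fusion

PCANet features number in the hundreds to thousands per view while cohorts
have tens of subjects, so plain CCA is singular. The implementation
standardizes each view, optionally PCA-reduces it (default to
min(m − 2, 64) dimensions; narrower views are left alone), adds a ridge
(default 1e-3, scaled by the mean covariance diagonal) to each within-view
covariance, and solves the canonical system by whitened SVD. Canonical
correlations are clipped to [0, 1] and come out non-increasing. The fused
vector is the concatenation of the two projected views by default
(`sum` is available); the number of pairs defaults to min(10, attainable).
Held-out data are transformed with stored statistics only.

## Classification and evaluation

Linear soft-margin SVM with C = 1 by default (high-dimensional features,
small n make linear the sensible default; RBF and the C grid are exposed),
one-vs-one for multiclass. The evaluation protocol is stratified 5-fold
cross-validation with a fixed seed: every learning step — PCANet banks,
CCA, SVM — is fitted inside the training fold only, and pooled test-fold
predictions give the confusion counts. A single-holdout mode is not the
default because with tens of subjects a lone split has very high variance.
Metrics follow the usual formulas; any ratio with a zero denominator is
reported as `None`, never silently 0. AUC is the midrank statistic over
decision scores (ties count half), equivalent to the trapezoidal ROC area;
for one-vs-one multiclass no single score exists and AUC is omitted.

## Phantom generator

Each subject is baseline 100 (so mask auto-detection behaves like real
BOLD scaling) plus unit-variance white noise, with two planted effects:

- `roi_alff` (a 5³ box): a sinusoid at 0.05 Hz — mid-band at TR = 2 s —
  with group-dependent amplitude (defaults 1.0 vs 3.0) and a random
  per-subject phase.
- `roi_reho` (a disjoint 5³ box): each voxel receives
  `2.0 · (w·z + (1−w)·p_v)` where `z` is one shared band-limited
  unit-variance series per subject, `p_v` a private one, and the mixing
  weight w is group-dependent (defaults 0.2 vs 0.8). With these defaults
  neighboring-voxel correlations are ≈0.04 vs ≈0.69, a strong and
  unambiguous concordance contrast; amplitude is the same in both groups,
  so the ReHo effect is pure coherence.

Grid 16³, 130 frames at TR 2 s (120 after dropping the first 10),
20 subjects per group. The cohort derives per-subject seeds from one root
seed. These sizes keep a full cross-validated run in the tens of seconds
on one CPU while leaving ≥24 training maps per fold for filter learning.

What the phantom does *not* emulate: anatomy and registration error,
physiological noise (cardiac/respiratory), motion, scanner drift beyond a
linear trend, multi-site effects, or spatially varying noise. Passing the
end-to-end checks therefore demonstrates that the implementation recovers
the signals it models — not that the method attains any particular accuracy
on clinical data.

## Numerical conventions and degenerate inputs

- Closed frequency interval; DC and Nyquist bins never enter ALFF.
- Kendall's W clamps tiny negative float noise to 0; degenerate inputs
  (T < 2, fewer than 2 series) are errors.
- Dividing a map by a zero or near-zero in-mask mean is an error naming
  the divisor, as is dropping every frame, a 3D file where 4D is expected,
  or a non-positive header TR (overridable by argument).
- All randomness (phantoms, fold shuffling) flows from explicit integer
  seeds; reruns with the same configuration are bitwise reproducible.

## Known limitations

- Tie-heavy (e.g. quantized) data lower W without the classical tie
  correction; integer-valued series should be dithered or avoided.
- The auto-mask is intensity-based only.
- CCA ridge/PCA defaults are sensible for tens of subjects; for m ≫ 100
  reduce the ridge or disable pre-reduction.
- PCANet memory grows with dense patch extraction; `patch_stride` trades
  fidelity of the learned filters for memory on large grids.
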
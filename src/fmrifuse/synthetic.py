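"""Synthetic 4D BOLD phantom cohorts with known group effects.

Each phantom subject is a baseline-100 volume plus white Gaussian noise,
with two planted, spatially disjoint effects whose strength depends on the
subject's group:

* an *amplitude* effect — a low-frequency sinusoid (default 0.05 Hz) of
  group-dependent amplitude and random subject phase inside ``roi_alff``,
  which raises ALFF/mALFF there;
* a *coherence* effect — every voxel of ``roi_reho`` receives a mixture
  ``w * z + (1 - w) * p_v`` of one shared band-limited latent series ``z``
  and a private band-limited series ``p_v``, scaled by a common amplitude.
  The group-dependent mixing weight ``w`` controls rank concordance among
  neighbors, which is what Kendall's W (ReHo) responds to, independent of
  amplitude.

The generator is fully deterministic given (config, group, seed); cohort
subjects draw their seeds from one root seed. Cardiac/respiratory confounds,
motion and anatomical geometry are deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alff import FrequencyBand, bandpass_series
from .volumes import Volume4D, write_volume4d

__all__ = ["PhantomConfig", "make_subject", "make_cohort", "write_cohort"]

_BOX = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom cohort.

    Defaults define the strong-effect two-group condition: 16^3 grid, 130
    frames at TR 2 s (so dropping the 10 unstable initial frames leaves
    120), oscillation at 0.05 Hz inside the 0.01-0.08 Hz band, amplitude
    3.0 vs 1.0 between groups, coherence weight 0.8 vs 0.2, unit noise.
    """

    grid: tuple[int, int, int] = (16, 16, 16)
    t_points: int = 130
    tr_seconds: float = 2.0
    roi_alff: _BOX = ((2, 7), (2, 7), (2, 7))
    roi_reho: _BOX = ((9, 14), (9, 14), (9, 14))
    alff_amp_by_group: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "patient": 3.0}
    )
    coherence_by_group: dict[str, float] = field(
        default_factory=lambda: {"control": 0.2, "patient": 0.8}
    )
    osc_freq_hz: float = 0.05
    coherence_amp: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not 0 < self.osc_freq_hz < nyquist:
            raise ValueError(
                f"osc_freq_hz={self.osc_freq_hz} outside (0, Nyquist={nyquist})"
            )
        for name, box in (("roi_alff", self.roi_alff), ("roi_reho", self.roi_reho)):
            for axis, (lo, hi) in enumerate(box):
                if not 0 <= lo < hi <= self.grid[axis]:
                    raise ValueError(f"{name} box {box} outside grid {self.grid}")
        if self._boxes_overlap():
            raise ValueError("roi_alff and roi_reho must be disjoint")
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if set(self.alff_amp_by_group) != set(self.coherence_by_group):
            raise ValueError("group label sets of the two effect maps differ")

    def _boxes_overlap(self) -> bool:
        return all(
            a_lo < b_hi and b_lo < a_hi
            for (a_lo, a_hi), (b_lo, b_hi) in zip(self.roi_alff, self.roi_reho)
        )

    @property
    def groups(self) -> list[str]:
        return sorted(self.alff_amp_by_group)

    def null(self) -> "PhantomConfig":
        """Zero-effect variant: both groups share the mean effect levels."""
        amp = float(np.mean(list(self.alff_amp_by_group.values())))
        coh = float(np.mean(list(self.coherence_by_group.values())))
        return replace(
            self,
            alff_amp_by_group={g: amp for g in self.alff_amp_by_group},
            coherence_by_group={g: coh for g in self.coherence_by_group},
        )


def _box_slices(box: _BOX) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in box)  # type: ignore[return-value]


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, ...],
                       tr: float) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to the 0.01-0.08 Hz band."""
    raw = rng.standard_normal(shape)
    band = FrequencyBand(0.01, 0.08)
    filtered = bandpass_series(raw, tr, band)
    sd = filtered.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filtered / sd


def make_subject(cfg: PhantomConfig, group: str, seed: int) -> Volume4D:
    """One deterministic phantom subject of the given group."""
    if group not in cfg.alff_amp_by_group:
        raise ValueError(f"unknown group {group!r}; known: {cfg.groups}")
    rng = np.random.default_rng(seed)
    t = np.arange(cfg.t_points)
    data = np.full((*cfg.grid, cfg.t_points), cfg.baseline, dtype=np.float64)

    # amplitude effect: group-scaled sinusoid, random subject phase
    amp = cfg.alff_amp_by_group[group]
    phase = rng.uniform(0, 2 * np.pi)
    osc = np.sin(2 * np.pi * cfg.osc_freq_hz * t * cfg.tr_seconds + phase)
    data[_box_slices(cfg.roi_alff)] += amp * osc

    # coherence effect: shared latent mixed into each ROI voxel
    w = cfg.coherence_by_group[group]
    reho_sl = _box_slices(cfg.roi_reho)
    roi_shape = data[reho_sl].shape
    latent = _bandlimited_noise(rng, (cfg.t_points,), cfg.tr_seconds)
    private = _bandlimited_noise(rng, roi_shape, cfg.tr_seconds)
    data[reho_sl] += cfg.coherence_amp * (w * latent + (1.0 - w) * private)

    data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    return Volume4D(data=data, tr_seconds=cfg.tr_seconds)


def make_cohort(cfg: PhantomConfig) -> list[tuple[str, str, Volume4D]]:
    """Balanced cohort as (subject_id, label, volume) tuples.

    Per-subject seeds derive from ``cfg.seed`` through a SeedSequence, so
    the cohort is reproducible and subjects are independent.
    """
    n_subjects = cfg.n_per_group * len(cfg.groups)
    children = np.random.SeedSequence(cfg.seed).spawn(n_subjects)
    cohort = []
    i = 0
    for group in cfg.groups:
        for j in range(cfg.n_per_group):
            seed = int(children[i].generate_state(1)[0] % (2**31))
            cohort.append((f"{group}_{j:03d}", group, make_subject(cfg, group, seed)))
            i += 1
    return cohort


def write_cohort(cfg: PhantomConfig, out_dir: str | Path) -> Path:
    """Write NIfTI volumes, a manifest CSV (subject_id, label, path) and a
    ground-truth JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject_id, label, vol in make_cohort(cfg):
        path = out_dir / f"{subject_id}.nii.gz"
        write_volume4d(vol, path)
        rows.append({"subject_id": subject_id, "label": label, "path": str(path)})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    truth = {
        "grid": cfg.grid,
        "t_points": cfg.t_points,
        "tr_seconds": cfg.tr_seconds,
        "roi_alff": cfg.roi_alff,
        "roi_reho": cfg.roi_reho,
        "alff_amp_by_group": cfg.alff_amp_by_group,
        "coherence_by_group": cfg.coherence_by_group,
        "osc_freq_hz": cfg.osc_freq_hz,
        "coherence_amp": cfg.coherence_amp,
        "noise_sd": cfg.noise_sd,
        "n_per_group": cfg.n_per_group,
        "seed": cfg.seed,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest
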
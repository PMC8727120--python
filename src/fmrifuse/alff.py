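"""Amplitude of low-frequency fluctuation (ALFF) and its normalized map mALFF.

ALFF summarizes how much slow spontaneous activity a voxel's BOLD series
carries: after removing the linear drift, the series is Fourier-transformed,
the square root of the periodogram power (``|DFT|^2 / T``) is taken at each
frequency bin inside the low-frequency band (default 0.01-0.08 Hz), and those
amplitudes are averaged. Selecting in-band periodogram bins is algebraically
identical to an ideal FFT-mask bandpass followed by a full-spectrum RMS, so
the bandpass step is folded into the bin selection. mALFF divides the ALFF
map by its whole-brain (in-mask) mean, making it a unitless relative map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import BrainMask, Volume3D, Volume4D, normalize_map_by_mask_mean

__all__ = [
    "FrequencyBand",
    "detrend_linear",
    "compute_alff",
    "alff_map",
    "malff_map",
    "bandpass_series",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A closed frequency interval [f_low, f_high] in Hz, with 0 < f_low."""

    f_low: float = 0.01
    f_high: float = 0.08

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"need 0 < f_low < f_high, got [{self.f_low}, {self.f_high}]"
            )

    def validate_for(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.f_high > nyquist:
            raise ValueError(
                f"f_high={self.f_high} Hz exceeds Nyquist {nyquist} Hz for TR={tr_seconds} s"
            )

    def bin_mask(self, n_times: int, tr_seconds: float) -> np.ndarray:
        """Boolean mask over rfft bins: in-band, excluding DC and Nyquist."""
        freqs = np.fft.rfftfreq(n_times, d=tr_seconds)
        nyquist = 1.0 / (2.0 * tr_seconds)
        mask = (freqs >= self.f_low) & (freqs <= self.f_high)
        mask &= freqs > 0
        mask &= freqs < nyquist
        return mask


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (intercept + slope) from a series.

    Works on the last axis, so a whole 4D volume can be detrended at once.
    The residual is orthogonal to both the constant and the linear ramp.
    """
    ts = np.asarray(ts, dtype=np.float64)
    t_len = ts.shape[-1]
    if t_len < 3:
        raise ValueError(f"detrending needs T >= 3 points, got T={t_len}")
    t = np.arange(t_len, dtype=np.float64)
    t_c = t - t.mean()
    mean = ts.mean(axis=-1, keepdims=True)
    slope = (ts * t_c).sum(axis=-1, keepdims=True) / (t_c**2).sum()
    return ts - mean - slope * t_c


def _alff_from_series(series: np.ndarray, tr: float, band: FrequencyBand) -> np.ndarray:
    """Vectorized ALFF over the last (time) axis of ``series``."""
    t_len = series.shape[-1]
    if t_len < 8:
        raise ValueError(f"ALFF needs T >= 8 points, got T={t_len}")
    band.validate_for(tr)
    bins = band.bin_mask(t_len, tr)
    if not bins.any():
        raise ValueError(
            f"no frequency bins inside [{band.f_low}, {band.f_high}] Hz "
            f"for T={t_len}, TR={tr} s"
        )
    detrended = detrend_linear(series)
    spectrum = np.fft.rfft(detrended, axis=-1)
    power = np.abs(spectrum) ** 2 / t_len
    amplitude = np.sqrt(power[..., bins])
    return amplitude.mean(axis=-1)


def compute_alff(ts: np.ndarray, tr: float, band: FrequencyBand) -> float:
    """ALFF of a single time series: mean in-band square-root periodogram power."""
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 1:
        raise ValueError(f"expected a 1D series, got shape {ts.shape}")
    return float(_alff_from_series(ts, tr, band))


def alff_map(v: Volume4D, mask: BrainMask, band: FrequencyBand) -> Volume3D:
    """Voxelwise ALFF inside the mask; out-of-mask voxels are 0."""
    if v.spatial_shape != mask.data.shape:
        raise ValueError(f"volume {v.spatial_shape} and mask {mask.data.shape} disagree")
    out = np.zeros(v.spatial_shape, dtype=np.float64)
    series = v.data[mask.data]  # (n_voxels, T)
    out[mask.data] = _alff_from_series(series, v.tr_seconds, band)
    return Volume3D(data=out, spacing_mm=v.spacing_mm)


def malff_map(v: Volume4D, mask: BrainMask, band: FrequencyBand) -> Volume3D:
    """mALFF: the ALFF map divided by its in-mask mean (whole-brain mean 1)."""
    return normalize_map_by_mask_mean(alff_map(v, mask, band), mask)


def bandpass_series(series: np.ndarray, tr: float, band: FrequencyBand) -> np.ndarray:
    """Ideal FFT-mask bandpass over the last axis, keeping in-band bins only.

    Used by the band-limited ReHo variants; DC and Nyquist are always removed.
    """
    series = np.asarray(series, dtype=np.float64)
    t_len = series.shape[-1]
    band.validate_for(tr)
    bins = band.bin_mask(t_len, tr)
    if not bins.any():
        raise ValueError(
            f"no frequency bins inside [{band.f_low}, {band.f_high}] Hz "
            f"for T={t_len}, TR={tr} s"
        )
    spectrum = np.fft.rfft(series, axis=-1)
    spectrum[..., ~bins] = 0.0
    return np.fft.irfft(spectrum, n=t_len, axis=-1)
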
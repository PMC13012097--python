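"""Morlet wavelet time–frequency power and infraslow band power.

Complex Morlet wavelets (a complex exponential under a Gaussian envelope,
constant 8 cycles, unit energy, support ±4 SD) are convolved with each
signal on a 50-step logarithmic grid from 0.01 to 5 Hz; squared magnitude
gives time-resolved power.  Epochs are mirror-extended once on each side
before convolution so the slowest kernels — which are longer than a 2-min
epoch — do not suffer edge roll-off; frequencies with fewer than two cycles
per epoch are flagged as low-quality.  Band power integrates the
time-collapsed spectrum over 0.01–0.08 Hz by the rectangle rule with bin
widths taken from the geometric midpoints of the log grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

__all__ = [
    "FreqGrid",
    "TFSpectrum",
    "BandPower",
    "morlet_kernel",
    "tf_power",
    "band_power",
    "subsample_voxels",
    "group_spectrum",
]


def _default_freqs() -> np.ndarray:
    return np.logspace(np.log10(0.01), np.log10(5.0), 50)


@dataclass(frozen=True)
class FreqGrid:
    """50 log-spaced analysis frequencies, 0.01–5 Hz, 8 wavelet cycles."""

    frequencies: np.ndarray = field(default_factory=_default_freqs)
    n_cycles: float = 8.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def bin_widths(self) -> np.ndarray:
        """Rectangle-rule widths from geometric midpoints of the log grid."""
        logf = np.log(self.frequencies)
        mids = 0.5 * (logf[:-1] + logf[1:])
        edges = np.concatenate([[2 * logf[0] - mids[0]], mids, [2 * logf[-1] - mids[-1]]])
        return np.diff(np.exp(edges))


@dataclass
class TFSpectrum:
    """Time–frequency power: shape (..., n_freqs, n_times), units signal²."""

    power: np.ndarray
    grid: FreqGrid
    fs: float
    quality: np.ndarray | None = None   # per-frequency: >= 2 cycles in epoch


@dataclass
class BandPower:
    """Frequency-integrated, time-averaged power over a band."""

    value: float | np.ndarray
    band: tuple[float, float] = (0.01, 0.08)


def morlet_kernel(f: float, n_cycles: float = 8.0, fs: float = 10.0) -> np.ndarray:
    """Complex Morlet wavelet at frequency ``f``.

    Gaussian envelope SD is ``n_cycles / (2 pi f)`` seconds; support ±4 SD;
    normalized to unit energy (sum |k|² = 1).
    """
    if f > fs / 2 * (1 + 1e-9):
        raise ValueError("kernel frequency exceeds Nyquist")
    if f <= 0:
        raise ValueError("kernel frequency must be positive")
    sd_t = n_cycles / (2 * np.pi * f)
    half = int(round(4 * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sd_t ** 2))
    return k / np.sqrt(np.sum(np.abs(k) ** 2))


def tf_power(x: np.ndarray, grid: FreqGrid | None = None, fs: float = 10.0) -> TFSpectrum:
    """Wavelet time–frequency power of 1D or (channels, t) signals.

    The signal is mirrored once on each side (whole reflection) before
    convolution; power is returned at the original sample times.
    """
    if grid is None:
        grid = FreqGrid()
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("signal too short for time-frequency analysis")
    padded = np.concatenate([x[..., ::-1], x, x[..., ::-1]], axis=-1)
    np_len = padded.shape[-1]
    kernels = [morlet_kernel(f, grid.n_cycles, fs) for f in grid.frequencies]
    max_len = max(k.size for k in kernels)
    nfft = sfft.next_fast_len(np_len + max_len - 1, real=False)
    X = sfft.fft(padded, nfft, axis=-1)
    power = np.empty(x.shape[:-1] + (len(kernels), n))
    for i, k in enumerate(kernels):
        f = grid.frequencies[i]
        # unit gain for a tone at the kernel's centre frequency, so power
        # is in signal units squared and a tone peaks at its own frequency
        t_k = (np.arange(k.size) - (k.size - 1) / 2) / fs
        gain = np.abs(np.sum(k * np.exp(-2j * np.pi * f * t_k))) / 2.0
        K = sfft.fft(k, nfft)
        y = sfft.ifft(X * K, axis=-1)
        # 'same'-mode alignment of the full convolution, then drop the pads
        start = (k.size - 1) // 2 + n
        seg = y[..., start:start + n]
        power[..., i, :] = np.abs(seg / gain) ** 2
    quality = grid.frequencies * (n / fs) >= 2.0
    if squeeze:
        power = power[0]
    return TFSpectrum(power=power, grid=grid, fs=fs, quality=quality)


def band_power(tf: TFSpectrum, band: tuple[float, float] = (0.01, 0.08)) -> BandPower:
    """Time-average the spectrum, then rectangle-integrate over ``band``."""
    f = tf.grid.frequencies
    lo, hi = band
    if lo < f[0] * 0.999 or hi > f[-1] * 1.001:
        raise ValueError("band outside the frequency grid")
    in_band = (f >= lo) & (f <= hi)
    if not np.any(in_band):
        raise ValueError("no grid frequencies inside band")
    mean_pow = tf.power.mean(axis=-1)            # (..., n_freqs)
    w = tf.grid.bin_widths()
    value = (mean_pow[..., in_band] * w[in_band]).sum(axis=-1)
    if np.ndim(value) == 0:
        value = float(value)
    return BandPower(value=value, band=band)


def subsample_voxels(
    mask: np.ndarray,
    fraction: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Uniform random in-mask voxel subsample, without replacement.

    Returns sorted flat indices into the volume; ``round(fraction * n_mask)``
    of them; deterministic for a given seed/Generator.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    in_mask = np.flatnonzero(np.asarray(mask, dtype=bool))
    if in_mask.size == 0:
        raise ValueError("empty mask")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = int(np.rint(fraction * in_mask.size))
    chosen = rng.choice(in_mask, size=k, replace=False)
    return np.sort(chosen)


def group_spectrum(curves_by_state: dict[str, list[np.ndarray]]) -> dict[str, dict[str, np.ndarray]]:
    """Per-state median and 25–75% envelope of per-subject power curves.

    Input: for each state, a list of per-subject power-vs-frequency curves
    (each subject already averaged over its sampled voxels / electrodes and
    over time).  Output: state -> {"median", "q25", "q75"} arrays.
    """
    out = {}
    for state, curves in curves_by_state.items():
        if not curves:
            raise ValueError(f"state {state!r} has no spectra")
        stack = np.vstack([np.asarray(c, dtype=float) for c in curves])
        out[state] = {
            "median": np.median(stack, axis=0),
            "q25": np.percentile(stack, 25, axis=0),
            "q75": np.percentile(stack, 75, axis=0),
        }
    return out
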
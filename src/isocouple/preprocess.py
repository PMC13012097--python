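"""Band-limiting, resampling, epoching, and optical-density conversion.

The infraslow band of interest is 0.01–0.08 Hz.  Band-limiting uses a long
Hamming-window FIR filter (order 3000 at 10 Hz) applied twice — once
forward, once backward, which for the symmetric taps amounts to convolving
twice — so the net response is zero-phase with squared magnitude.  Edge
effects are avoided by mirror-extending the signal by at least one filter
order on each side before filtering; the extension tiles whole reflected
copies, so records shorter than the filter remain filterable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Mapping

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "Epoch",
    "OpticalCalibration",
    "design_fir",
    "filter_band",
    "decimate_to",
    "extract_state_epochs",
    "mbll_concentrations",
]


@dataclass(frozen=True)
class FilterSpec:
    """Hamming-window FIR band-pass specification (zero-phase use)."""

    order: int = 3000
    band: tuple[float, float] = (0.01, 0.08)
    fs: float = 10.0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.order % 2 != 0:
            raise ValueError("order must be even for a symmetric linear-phase design")
        lo, hi = self.band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("band must lie strictly inside (0, Nyquist)")


@dataclass
class Epoch:
    """A single-state, fixed-length synchronized segment."""

    state: str
    signals: Mapping[str, np.ndarray] | np.ndarray
    onset_s: float
    subject_id: str | None = None


@dataclass
class OpticalCalibration:
    """Modified Beer–Lambert calibration for a 3-wavelength NIRS setup.

    ``extinction`` is the 3x3 matrix of extinction coefficients, rows =
    wavelengths (690, 830, 980 nm), columns = chromophores (Hb, HbO, H2O);
    ``pathlength`` is the source–detector separation in cm and ``dpf`` the
    per-wavelength differential pathlength factors.  Real-optics users must
    supply their own coefficients; the identity default only suits synthetic
    fixtures.
    """

    extinction: np.ndarray = field(default_factory=lambda: np.eye(3))
    pathlength: float = 3.0
    dpf: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (3, 3):
            raise ValueError("extinction must be 3x3")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")


def design_fir(spec: FilterSpec) -> np.ndarray:
    """Design the band-pass taps; length ``order + 1``, symmetric."""
    return sps.firwin(
        spec.order + 1,
        list(spec.band),
        pass_zero=False,
        window=spec.window,
        fs=spec.fs,
    )


def _mirror_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Extend ``x`` by ``pad`` samples each side with whole-block mirroring.

    Blocks alternate reversed/forward copies so the extension is continuous
    at the edges and works for any ``pad``, including pad > len(x).
    """
    n = x.shape[-1]
    reps = -(-pad // n)  # ceil
    left_blocks, right_blocks = [], []
    flip = True
    for _ in range(reps):
        left_blocks.insert(0, x[..., ::-1] if flip else x)
        right_blocks.append(x[..., ::-1] if flip else x)
        flip = not flip
    left = np.concatenate(left_blocks, axis=-1)[..., -pad:]
    right = np.concatenate(right_blocks, axis=-1)[..., :pad]
    return np.concatenate([left, x, right], axis=-1)


def filter_band(x: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase band-pass along the last axis; output length == input.

    Mirror-extends by one filter order per side, convolves with the
    symmetric FIR taps twice (equivalent to forward–backward filtering),
    and removes the padding.
    """
    if spec is None:
        spec = FilterSpec()
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("signal too short to filter")
    taps = design_fir(spec)
    pad = spec.order
    ext = _mirror_extend(x, pad)
    kern = taps.reshape((1,) * (x.ndim - 1) + (-1,))
    y = sps.fftconvolve(ext, kern, mode="same", axes=-1)
    y = sps.fftconvolve(y, kern, mode="same", axes=-1)
    return y[..., pad:pad + n]


def decimate_to(x: np.ndarray, fs_in: float, fs_out: float = 10.0) -> np.ndarray:
    """Anti-alias low-pass then downsample from ``fs_in`` to ``fs_out``.

    The ratio must be an integer; large ratios are decimated in stages of
    at most 10 (FIR, zero-phase).  Output length is
    ``floor(n * fs_out / fs_in)``.
    """
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    x = np.asarray(x, dtype=float)
    n_target = int(np.floor(x.shape[-1] * fs_out / fs_in))
    if q == 1:
        return x.copy()
    y = x
    r = q
    while r > 1:
        stage = None
        for cand in range(min(10, r), 1, -1):
            if r % cand == 0:
                stage = cand
                break
        if stage is None:   # prime ratio > 10
            stage = r
        y = sps.decimate(y, stage, ftype="fir", zero_phase=True, axis=-1)
        r //= stage
    return y[..., :n_target]


def extract_state_epochs(
    hypnogram: list[str],
    signals: Mapping[str, np.ndarray] | np.ndarray,
    fs: float,
    epoch_len_s: float = 120.0,
    n_per_state: int = 1,
    subject_id: str | None = None,
) -> list[Epoch]:
    """Extract fixed-length single-state epochs from a scored recording.

    The hypnogram is a sequence of 30-s labels aligned to the signal start.
    For each state present, up to ``n_per_state`` non-overlapping epochs of
    exactly ``epoch_len_s`` are taken from the start of the *longest*
    continuous run of that state (earliest run on ties); states whose
    longest run is shorter than ``epoch_len_s`` yield no epoch.  All data
    outside the returned epochs are excluded.
    """
    arrays = signals if isinstance(signals, Mapping) else {"signal": signals}
    n = next(iter(arrays.values())).shape[-1]
    for a in arrays.values():
        if a.shape[-1] != n:
            raise ValueError("signals must share the time axis length")
    if len(hypnogram) * 30 * fs < n:
        raise ValueError("hypnogram shorter than the signals: misaligned scoring")
    # runs as (state, start_epoch, length_epochs)
    runs = []
    pos = 0
    for state, grp in groupby(hypnogram):
        length = len(list(grp))
        runs.append((state, pos, length))
        pos += length
    epochs: list[Epoch] = []
    seen: list[str] = []
    for state in dict.fromkeys(hypnogram):
        seen.append(state)
        state_runs = [r for r in runs if r[0] == state]
        best = max(state_runs, key=lambda r: r[2])  # max is stable: earliest longest
        run_len_s = best[2] * 30.0
        n_fit = min(n_per_state, int(run_len_s // epoch_len_s))
        for k in range(n_fit):
            onset_s = best[1] * 30.0 + k * epoch_len_s
            i0 = int(round(onset_s * fs))
            i1 = i0 + int(round(epoch_len_s * fs))
            if i1 > n:
                break
            sliced = {name: a[..., i0:i1] for name, a in arrays.items()}
            if not isinstance(signals, Mapping):
                sliced = sliced["signal"]
            epochs.append(Epoch(state=state, signals=sliced, onset_s=onset_s,
                                subject_id=subject_id))
    return epochs


def mbll_concentrations(absorbance_change: np.ndarray, cal: OpticalCalibration) -> np.ndarray:
    """Modified Beer–Lambert inversion: absorbance changes -> concentrations.

    ``dC[:, t] = (E L)^-1 dA[:, t]`` with ``L = diag(pathlength * dpf)``;
    exactly linear in the absorbance changes.
    """
    dA = np.asarray(absorbance_change, dtype=float)
    if dA.shape[0] != 3:
        raise ValueError("absorbance_change must be 3 x t")
    L = np.diag(cal.pathlength * np.asarray(cal.dpf, dtype=float))
    M = cal.extinction @ L
    if np.linalg.cond(M) > 1e12:
        raise np.linalg.LinAlgError("extinction * pathlength matrix is singular")
    return np.linalg.solve(M, dA)
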
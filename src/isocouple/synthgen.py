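"""Synthetic multimodal recordings with known directed infraslow coupling.

Three latent infraslow oscillators — ELEC (electrophysiological), BLOOD
(hemodynamic / blood volume), WATER (tissue-water concentration) — evolve as
noisy phase oscillators with Kuramoto-style sinusoidal coupling acting on a
*delayed* copy of the driving phase.  Directed coupling ``kappa[j -> i]``
makes oscillator ``i``'s phase track oscillator ``j``'s phase one cycle back,
so the driver's innovations appear in the target later: exactly the
structure that phase transfer entropy is designed to detect.  Amplitude and
phase dynamics are kept separate because the downstream analysis is purely
phase-based.

The rendered recording emulates a 10 Hz multimodal acquisition: a small
voxel grid with spatially smooth hemodynamic loadings ("BOLD"), a handful
of electrode channels ("EEG"), a 3-channel optical concentration series
(Hb, HbO, H2O) in which the water channel can load negatively on blood
volume (Monro–Kellie-style anticorrelation), a 30-s hypnogram, and a 9-label
region atlas.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "LATENTS",
    "STATES",
    "ROI_NAMES",
    "SyntheticConfig",
    "MultimodalRecording",
    "SpatialModel",
    "make_spatial",
    "simulate_coupled_latents",
    "render_recording",
    "generate_subject",
]

#: latent order used everywhere: index 0 = ELEC, 1 = BLOOD, 2 = WATER
LATENTS = ("ELEC", "BLOOD", "WATER")

#: recognised arousal-state labels (AASM-style wake / NREM-1 / NREM-2)
STATES = ("AWAKE", "N1", "N2")

#: the nine bilateral regions the atlas partitions the mask into
ROI_NAMES = {
    1: "caudate",
    2: "cerebellum",
    3: "frontal lobe",
    4: "insula",
    5: "occipital lobe",
    6: "parietal lobe",
    7: "putamen",
    8: "temporal lobe",
    9: "thalamus",
}

#: optical channel order of the ``nirs`` array
NIRS_CHANNELS = ("Hb", "HbO", "H2O")


def _default_kappa() -> dict[str, np.ndarray]:
    """Per-state 3x3 coupling matrices, ``K[i, j]`` = strength of j -> i.

    Awake: one-way neurovascular / hydro-vascular drive (ELEC -> BLOOD and
    WATER -> BLOOD).  Sleep: the same links made symmetric (bidirectional)
    so the net drive cancels.  An EEG-over-water prediction preponderance
    still emerges in the rendered channels through the hemodynamic loading
    of the optical water channel, so no direct ELEC -> WATER link is needed.
    """
    e, b, w = 0, 1, 2
    awake = np.zeros((3, 3))
    awake[b, e] = 0.3
    awake[b, w] = 0.3
    sleep = np.zeros((3, 3))
    sleep[b, e] = sleep[e, b] = 0.15
    sleep[b, w] = sleep[w, b] = 0.15
    return {"AWAKE": awake, "N1": sleep.copy(), "N2": sleep.copy()}


def _default_power_scale() -> dict[str, tuple[float, float, float]]:
    # amplitudes (ELEC, BLOOD, WATER); sleep roughly doubles infraslow
    # electrical and hemodynamic band power (amplitude ~ sqrt(2..2.5))
    # while the water channel's power is state-independent
    return {
        "AWAKE": (1.0, 1.0, 1.0),
        "N1": (1.6, 1.5, 1.0),
        "N2": (1.7, 1.5, 1.0),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic multimodal generator.

    Parameters
    ----------
    fs : sampling rate in Hz of every modality.
    epoch_len_s : length of one state-specific epoch, seconds.
    n_epochs_per_state : contiguous epochs simulated per state.
    states : ordered arousal states to simulate.
    osc_band : (lo, hi) Hz, the infraslow band of interest.
    f_center : Hz, centre frequency of the latent oscillators and the
        frequency defining the one-cycle coupling/analysis delay.
    kappa : per-state 3x3 directed coupling strengths, ``kappa[state][i, j]``
        is the pull of latent ``j`` on latent ``i`` (rad per sample at full
        phase misalignment).
    power_scale : per-state amplitude multipliers for (ELEC, BLOOD, WATER).
    anticorr_water : if True the optical water channel loads negatively on
        the BLOOD latent.
    grid_shape : voxel grid of the rendered hemodynamic volume.
    n_electrodes : electrode count of the rendered electrical channels.
    noise_sd : SD of the broadband white noise added to latents, voxels and
        channels (signal amplitudes are O(1)).
    phase_noise_sd : per-step SD of the phase random walk, radians.
    freq_jitter : relative half-width of the uniform jitter applied to each
        latent's natural frequency around ``f_center``.
    nuisance : amplitudes of the (1 Hz "cardiac", 0.25 Hz "respiratory")
        nuisance tones added to rendered channels.
    seed : RNG seed; identical config => bit-identical recording.
    """

    fs: float = 10.0
    epoch_len_s: float = 120.0
    n_epochs_per_state: int = 1
    states: Sequence[str] = ("AWAKE", "N1", "N2")
    osc_band: tuple[float, float] = (0.01, 0.08)
    f_center: float = 0.03
    kappa: Mapping[str, np.ndarray] = field(default_factory=_default_kappa)
    power_scale: Mapping[str, Sequence[float]] = field(default_factory=_default_power_scale)
    anticorr_water: bool = True
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_electrodes: int = 16
    noise_sd: float = 0.5
    phase_noise_sd: float = 0.1
    freq_jitter: float = 0.1
    nuisance: tuple[float, float] = (0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.osc_band
        if not 0 < lo < hi:
            raise ValueError("osc_band must satisfy 0 < lo < hi")
        if self.fs <= 2 * hi:
            raise ValueError("fs must exceed twice the upper band edge")
        if not 0 < self.f_center < self.fs / 2:
            raise ValueError("f_center must lie inside (0, Nyquist)")
        if self.epoch_len_s * self.f_center <= 1:
            raise ValueError("epoch must exceed one cycle at f_center")
        for st in self.states:
            if st not in STATES:
                raise ValueError(f"unknown state label {st!r}")
            K = np.asarray(self.kappa[st], dtype=float)
            if K.shape != (3, 3) or not np.all(np.isfinite(K)) or np.any(K < 0):
                raise ValueError("kappa must be a finite non-negative 3x3 matrix per state")
            ps = np.asarray(self.power_scale[st], dtype=float)
            if ps.shape != (3,) or np.any(ps <= 0):
                raise ValueError("power_scale must be 3 positive values per state")

    @property
    def n_samples_per_state(self) -> int:
        return int(round(self.epoch_len_s * self.fs)) * self.n_epochs_per_state

    def lag_samples(self) -> int:
        """One cycle at ``f_center``, in samples."""
        return int(round(self.fs / self.f_center))


@dataclass
class SpatialModel:
    """Subject-level spatial structure shared across arousal states."""

    mask: np.ndarray        # bool (x, y, z)
    atlas: np.ndarray       # int (x, y, z), labels 1..9, 0 background
    loading: np.ndarray     # float (x, y, z), hemodynamic voxel loading
    eeg_gain: np.ndarray    # float (n_electrodes,)


@dataclass
class MultimodalRecording:
    """Synchronised 10 Hz voxel-volume, electrode, and optical series."""

    bold: np.ndarray            # (x, y, z, t)
    mask: np.ndarray            # bool (x, y, z)
    eeg: np.ndarray             # (n_electrodes, t)
    nirs: np.ndarray            # (3, t): Hb, HbO, H2O
    hypnogram: list[str]        # 30-s state labels
    fs: float
    atlas: np.ndarray           # int (x, y, z)

    def __post_init__(self) -> None:
        t = self.bold.shape[-1]
        if self.eeg.shape[-1] != t or self.nirs.shape[-1] != t:
            raise ValueError("all modalities must share the time axis length")
        if len(self.hypnogram) * 30 * self.fs < t:
            raise ValueError("hypnogram does not cover the recording")
        if self.atlas.shape != self.mask.shape or self.bold.shape[:3] != self.mask.shape:
            raise ValueError("atlas/mask/bold grids disagree")
        labels = np.unique(self.atlas[self.atlas != 0])
        if labels.size and not np.all(np.isin(labels, np.arange(1, 10))):
            raise ValueError("atlas labels must be in 1..9")

    @property
    def n_samples(self) -> int:
        return self.bold.shape[-1]


def make_spatial(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SpatialModel:
    """Draw per-subject mask, 9-label atlas, voxel loadings, electrode gains.

    The atlas partitions the (full-grid) mask into nine contiguous index
    blocks standing in for the nine bilateral anatomical regions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mask = np.ones(config.grid_shape, dtype=bool)
    if mask.sum() < 9:
        raise ValueError("grid too small to hold 9 nonempty ROI labels")
    atlas = np.zeros(config.grid_shape, dtype=np.int16)
    flat = np.flatnonzero(mask)
    for label, chunk in enumerate(np.array_split(flat, 9), start=1):
        atlas.ravel()[chunk] = label
    smooth = gaussian_filter(rng.standard_normal(config.grid_shape), sigma=2.0)
    smooth /= max(np.abs(smooth).max(), 1e-12)
    loading = 1.0 + 0.5 * smooth            # positive, spatially smooth
    eeg_gain = 1.0 + 0.2 * rng.uniform(-1.0, 1.0, config.n_electrodes)
    return SpatialModel(mask=mask, atlas=atlas, loading=loading, eeg_gain=eeg_gain)


def simulate_coupled_latents(
    config: SyntheticConfig,
    state: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the three coupled latent series for one arousal state.

    Each latent is ``a * cos(theta_i[n]) + broadband noise`` where the phases
    follow

        theta_i[n+1] = theta_i[n] + 2 pi f_i / fs
                       + sum_j kappa[j->i] sin(theta_j[n - delta] - theta_i[n])
                       + phase_noise_sd * xi[n],

    with natural frequencies ``f_i`` jittered around ``f_center`` and the
    coupling delay ``delta`` equal to one cycle at ``f_center``.  Returns an
    array of shape ``(3, n_samples_per_state)`` ordered (ELEC, BLOOD, WATER).
    Deterministic given the RNG (default: seeded from ``config.seed``).
    """
    if state not in config.states and state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K = np.asarray(config.kappa[state], dtype=float)
    if np.any(K.sum(axis=1) >= np.pi):
        raise ValueError("kappa rows sum to >= pi per step: phase update would destabilize")
    n_out = config.n_samples_per_state
    delta = config.lag_samples()
    burn = 3 * delta                         # let coupling reach lock
    n_tot = n_out + burn
    f = config.f_center * (1.0 + config.freq_jitter * rng.uniform(-1.0, 1.0, 3))
    step = 2.0 * np.pi * f / config.fs
    phase_noise = config.phase_noise_sd * rng.standard_normal((3, n_tot))
    theta = np.empty((3, n_tot))
    theta[:, 0] = rng.uniform(-np.pi, np.pi, 3)
    coupled = np.any(K > 0)
    for t in range(n_tot - 1):
        cur = theta[:, t]
        drift = step + phase_noise[:, t]
        if coupled and t >= delta:
            past = theta[:, t - delta]
            drift = drift + (K * np.sin(past[None, :] - cur[:, None])).sum(axis=1)
        theta[:, t + 1] = cur + drift
    amp = np.asarray(config.power_scale[state], dtype=float)
    latents = amp[:, None] * np.cos(theta[:, burn:])
    if config.noise_sd > 0:
        latents = latents + config.noise_sd * rng.standard_normal((3, n_out))
    return latents


def _nuisance_tones(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Shared cardiorespiratory nuisance signal (1 Hz + 0.25 Hz tones)."""
    t = np.arange(n) / config.fs
    a_card, a_resp = config.nuisance
    sig = np.zeros(n)
    if a_card > 0:
        sig += a_card * np.cos(2 * np.pi * 1.0 * t + rng.uniform(0, 2 * np.pi))
    if a_resp > 0:
        sig += a_resp * np.cos(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    return sig


# fixed mixing gains of the rendered optical channels onto the latents;
# venous Hb swings are kept smaller than arterial HbO, and the water
# channel keeps its own WATER content beside the (anti)correlated blood
# part (kept moderate so the water channel is not dominated by blood)
_G_HBO = 1.0
_G_HB = -0.3
_G_H2O_BLOOD = 0.2
_G_H2O_WATER = 1.0


def render_recording(
    latents: np.ndarray,
    config: SyntheticConfig,
    state: str,
    rng: np.random.Generator | None = None,
    spatial: SpatialModel | None = None,
) -> MultimodalRecording:
    """Project latent series into a voxel grid, electrodes, and optics.

    BOLD voxels are ``loading * BLOOD + noise + nuisance``; EEG channels are
    ``gain * ELEC + noise + nuisance``; the optical water channel is
    ``-0.2 * BLOOD + WATER + noise`` when ``anticorr_water`` (so it
    anticorrelates with the HbO channel, which is ``+BLOOD``), else plain
    ``WATER``.  The hypnogram is filled with ``state``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if spatial is None:
        spatial = make_spatial(config, rng)
    lat = np.asarray(latents, dtype=float)
    if lat.shape[0] != 3:
        raise ValueError("latents must have shape (3, t)")
    elec, blood, water = lat
    n = lat.shape[1]
    sd = config.noise_sd
    nuis = _nuisance_tones(config, n, rng)

    bold = spatial.loading[..., None] * blood + nuis
    if sd > 0:
        bold = bold + sd * rng.standard_normal(bold.shape)

    eeg = spatial.eeg_gain[:, None] * elec + nuis
    if sd > 0:
        eeg = eeg + sd * rng.standard_normal(eeg.shape)

    hbo = _G_HBO * blood
    hb = _G_HB * blood
    if config.anticorr_water:
        h2o = -abs(_G_H2O_BLOOD) * blood + _G_H2O_WATER * water
    else:
        h2o = _G_H2O_WATER * water
    nirs = np.vstack([hb, hbo, h2o]) + nuis
    if sd > 0:
        nirs = nirs + sd * rng.standard_normal(nirs.shape)

    n_hyp = int(np.ceil(n / (30.0 * config.fs)))
    return MultimodalRecording(
        bold=bold,
        mask=spatial.mask,
        eeg=eeg,
        nirs=nirs,
        hypnogram=[state] * n_hyp,
        fs=config.fs,
        atlas=spatial.atlas,
    )


def generate_subject(config: SyntheticConfig, seed: int | None = None) -> MultimodalRecording:
    """One subject's recording: all configured states, concatenated in time.

    The spatial model (mask, atlas, loadings, gains) is drawn once per
    subject; each state's latent dynamics and rendering noise are drawn
    sequentially from the same stream, so the whole recording is
    deterministic given (config, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spatial = make_spatial(config, rng)
    per_state = [
        render_recording(simulate_coupled_latents(config, st, rng), config, st, rng, spatial)
        for st in config.states
    ]
    return MultimodalRecording(
        bold=np.concatenate([r.bold for r in per_state], axis=-1),
        mask=spatial.mask,
        eeg=np.concatenate([r.eeg for r in per_state], axis=-1),
        nirs=np.concatenate([r.nirs for r in per_state], axis=-1),
        hypnogram=sum([r.hypnogram for r in per_state], []),
        fs=config.fs,
        atlas=spatial.atlas,
    )
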
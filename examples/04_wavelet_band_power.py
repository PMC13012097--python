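"""Morlet wavelet spectra and infraslow band power across arousal states.

Sleep states are configured with larger hemodynamic/electrical oscillation
amplitudes; band power (0.01-0.08 Hz integral) scales with amplitude
squared.
"""
import numpy as np

from isocouple import (FreqGrid, SyntheticConfig, band_power,
                       simulate_coupled_latents, tf_power)

cfg = SyntheticConfig(states=("AWAKE", "N2"), seed=3)
grid = FreqGrid()
for state in cfg.states:
    lat = simulate_coupled_latents(cfg, state)
    tf = tf_power(lat[1], grid, cfg.fs)      # BLOOD latent
    bp = band_power(tf)
    peak = grid.frequencies[np.argmax(tf.power.mean(axis=-1))]
    print(f"{state:5s}: band power = {bp.value:6.3f} (signal^2 x Hz), "
          f"spectral peak at {peak:.3f} Hz")
print("-> N2 band power exceeds AWAKE (amplitude scale 1.5 -> power ~2.2x), "
      "peak near the 0.03 Hz oscillator frequency")
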
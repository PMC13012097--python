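"""Phase transfer entropy recovers an imposed coupling direction.

One-way coupling ELEC -> BLOOD is planted in the generator; the sign of
the net statistic dTE(BLOOD, ELEC) = TE(BLOOD->ELEC) - TE(ELEC->BLOOD)
then comes out negative: the electrical phase predicts the hemodynamic
phase, not vice versa.
"""
import numpy as np

from isocouple import (FilterSpec, SyntheticConfig, analytic_phase,
                       default_lag, discretize_phase, filter_band, phase_te,
                       simulate_coupled_latents)

K = np.zeros((3, 3))
K[1, 0] = 0.3                               # ELEC (index 0) drives BLOOD (1)
cfg = SyntheticConfig(states=("AWAKE",), kappa={"AWAKE": K},
                      n_epochs_per_state=3, seed=1)

lat = filter_band(simulate_coupled_latents(cfg, "AWAKE"), FilterSpec())
lat = lat[:, 1200:2400]                     # interior 2-min epoch
lag = default_lag(cfg.f_center, cfg.fs)     # one cycle at 0.03 Hz = 333 samples

sym = [discretize_phase(analytic_phase(x, cfg.fs), 8) for x in lat]
te = phase_te(sym[1], sym[0], lag=lag)      # x = BLOOD, y = ELEC
print(f"TE(BLOOD->ELEC) = {te.te_xy:.3f} bits")
print(f"TE(ELEC->BLOOD) = {te.te_yx:.3f} bits")
print(f"dTE             = {te.delta_te:+.3f} bits  "
      "(negative: ELEC predicts BLOOD, the planted direction)")

null = phase_te(sym[2], sym[0], lag=lag)    # WATER is uncoupled here
print(f"dTE(WATER, ELEC) = {null.delta_te:+.3f} bits "
      "(uncoupled pair: zero-mean, ~0.2-bit estimator noise at 2-min epochs)")
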
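"""Generate a synthetic multimodal recording and write it as NIfTI + TSV.

Three latent infraslow oscillators (electrical, hemodynamic, water) with
state-dependent directed coupling are rendered into a voxel volume, a set
of electrode channels, and a 3-channel optical series.
"""
import tempfile
from pathlib import Path

import numpy as np

from isocouple import SyntheticConfig, generate_subject
from isocouple.io import write_fixture

cfg = SyntheticConfig(states=("AWAKE", "N2"), grid_shape=(6, 6, 6),
                      n_electrodes=8, seed=42)
rec = generate_subject(cfg)

print(f"recording: {rec.bold.shape} BOLD grid, {rec.eeg.shape[0]} electrodes, "
      f"{rec.nirs.shape[0]} optical channels, fs = {rec.fs} Hz")
print(f"hypnogram (30-s labels): {rec.hypnogram}")
hb, hbo, h2o = rec.nirs
print(f"corr(H2O, HbO) = {np.corrcoef(h2o, hbo)[0, 1]:+.2f}  "
      "(negative: water anticorrelates with blood volume, Monro-Kellie)")

out = Path(tempfile.mkdtemp()) / "sub-01"
files = write_fixture(rec, out)
print(f"wrote {len(files)} files under {out}")
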
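"""Fixture I/O: NIfTI volumes and TSV channel tables for recordings.

File layout written by :func:`write_fixture` inside one directory::

    bold.nii       4D float64 volume (x, y, z, t)
    mask.nii       3D uint8 brain mask
    atlas.nii      3D int16 region labels (1..9, 0 background)
    eeg.tsv        tab-separated, header ``ch01..chNN``, one row per sample
    nirs.tsv       tab-separated, header ``Hb HbO H2O``
    hypnogram.tsv  columns ``epoch_index onset_s label``
    meta.json      {"fs": ...}

Floats are written with 17 significant digits so arrays round-trip
bit-identically through :func:`read_recording`.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthgen import MultimodalRecording

__all__ = ["write_fixture", "read_recording"]

_FLOAT_FMT = "%.17g"


def _write_tsv(path: Path, data: np.ndarray, columns: list[str]) -> None:
    # data: (channels, t) -> rows are samples
    header = "\t".join(columns)
    np.savetxt(path, np.asarray(data).T, fmt=_FLOAT_FMT, delimiter="\t",
               header=header, comments="")


def write_fixture(rec: MultimodalRecording, directory: str | Path) -> dict[str, Path]:
    """Write a recording to ``directory``; returns the file map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    files = {
        "bold": d / "bold.nii",
        "mask": d / "mask.nii",
        "atlas": d / "atlas.nii",
        "eeg": d / "eeg.tsv",
        "nirs": d / "nirs.tsv",
        "hypnogram": d / "hypnogram.tsv",
        "meta": d / "meta.json",
    }
    nib.save(nib.Nifti1Image(rec.bold.astype(np.float64), aff), files["bold"])
    nib.save(nib.Nifti1Image(rec.mask.astype(np.uint8), aff), files["mask"])
    nib.save(nib.Nifti1Image(rec.atlas.astype(np.int16), aff), files["atlas"])
    _write_tsv(files["eeg"], rec.eeg, [f"ch{i + 1:02d}" for i in range(rec.eeg.shape[0])])
    _write_tsv(files["nirs"], rec.nirs, ["Hb", "HbO", "H2O"])
    hyp = pd.DataFrame({
        "epoch_index": np.arange(len(rec.hypnogram)),
        "onset_s": 30.0 * np.arange(len(rec.hypnogram)),
        "label": list(rec.hypnogram),
    })
    hyp.to_csv(files["hypnogram"], sep="\t", index=False)
    files["meta"].write_text(json.dumps({"fs": rec.fs}, sort_keys=True))
    return files


def read_recording(directory: str | Path) -> MultimodalRecording:
    """Read a recording previously written by :func:`write_fixture`.

    NIfTI parsing is delegated to nibabel, so a corrupt magic number raises
    ``nibabel.filebasedimages.ImageFileError`` rather than yielding garbage.
    """
    d = Path(directory)
    bold = np.asarray(nib.load(d / "bold.nii").dataobj, dtype=np.float64)
    mask = np.asarray(nib.load(d / "mask.nii").dataobj).astype(bool)
    atlas = np.asarray(nib.load(d / "atlas.nii").dataobj).astype(np.int16)
    eeg = pd.read_csv(d / "eeg.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=np.float64).T
    nirs = pd.read_csv(d / "nirs.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=np.float64).T
    hyp = pd.read_csv(d / "hypnogram.tsv", sep="\t")
    meta = json.loads((d / "meta.json").read_text())
    return MultimodalRecording(
        bold=bold, mask=mask, eeg=eeg, nirs=nirs,
        hypnogram=[str(x) for x in hyp["label"]],
        fs=float(meta["fs"]), atlas=atlas,
    )
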
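"""End-to-end orchestration of the two headline analyses.

``run_power_analysis`` reproduces the spectral contrast: per-subject
infraslow (0.01–0.08 Hz) band power for every modality and state, compared
across arousal states with Wilcoxon rank-sum + FDR.

``run_coupling_analysis`` reproduces the directed-coupling contrast:
band-limited epochs, voxel/electrode phase-TE maps with the fixed sign
conventions, whole-brain / ROI / electrode aggregates, directional
components, Wilcoxon+FDR on the scalar aggregates, permutation/TFCE on the
voxel maps, and the seed-lag control analysis.

Both run from a :class:`RunConfig` that either embeds a synthetic-generator
block or points at fixture directories on disk, and both are deterministic
given the seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import io as fixture_io
from .coupling import (aggregate_te, default_lag, pairwise_te_map, xcorr_lag_map)
from .preprocess import FilterSpec, extract_state_epochs, filter_band
from .spectral import FreqGrid, band_power, subsample_voxels, tf_power
from .stats import TFCEParams, fdr_adjust, permutation_test, wilcoxon_ranksum
from .synthgen import MultimodalRecording, SyntheticConfig, generate_subject

__all__ = ["RunConfig", "PowerResult", "CouplingResult",
           "run_power_analysis", "run_coupling_analysis", "generate_fixtures"]

log = logging.getLogger("isocouple")

#: atlas label of the frontal region used as the lag-control seed
FRONTAL_LABEL = 3


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_dirs: list[str] | None = None     # fixture dirs, one per subject
    n_subjects: int = 20
    band: tuple[float, float] = (0.01, 0.08)
    n_bins: int = 8
    f_center: float = 0.03
    epoch_len_s: float = 120.0
    fir_order: int = 3000
    epochs_per_state: int = 1      # non-overlapping 2-min epochs per state
    subsample_fraction: float = 0.05
    n_perm: int = 5000
    tfce: TFCEParams = field(default_factory=TFCEParams)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_dirs is not None and self.n_subjects != len(self.input_dirs):
            self.n_subjects = len(self.input_dirs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            for key in ("kappa", "power_scale"):
                if key in syn:
                    syn[key] = {k: np.asarray(v, dtype=float) for k, v in syn[key].items()}
            for key in ("osc_band", "grid_shape", "nuisance", "states"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SyntheticConfig(**syn)
        if "tfce" in d and isinstance(d["tfce"], dict):
            d["tfce"] = TFCEParams(**d["tfce"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_jsonable(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj
        return conv(self)

    def run_id(self) -> str:
        payload = {k: v for k, v in self.to_jsonable().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class PowerResult:
    band_powers: pd.DataFrame
    spectra: pd.DataFrame
    contrasts: pd.DataFrame
    out_dir: Path | None = None


@dataclass
class CouplingResult:
    aggregates: pd.DataFrame          # per subject x state x pair x region
    contrasts: pd.DataFrame           # wilcoxon + FDR on scalar aggregates
    voxelwise: dict                   # (pair, contrast) -> PermutationResult
    delta_maps: dict                  # (pair, state) -> (n_subj, x, y, z)
    lag_control: pd.DataFrame
    electrodes: pd.DataFrame | None = None
    mask: np.ndarray | None = None
    out_dir: Path | None = None


def _subject_recordings(cfg: RunConfig):
    """Yield (subject_id, recording); synthetic subjects draw child seeds."""
    if cfg.input_dirs is not None:
        for i, d in enumerate(cfg.input_dirs):
            yield f"sub-{i + 1:02d}", fixture_io.read_recording(d)
    else:
        rng = np.random.default_rng(cfg.seed)
        seeds = rng.integers(2 ** 31, size=cfg.n_subjects)
        for i, s in enumerate(seeds):
            yield f"sub-{i + 1:02d}", generate_subject(cfg.synthetic, int(s))


def _state_contrast_pairs(states: list[str]) -> list[tuple[str, str]]:
    return list(combinations(states, 2))


def run_power_analysis(cfg: RunConfig,
                       modalities: tuple[str, ...] = ("bold", "eeg", "nirs_h2o")) -> PowerResult:
    """Per-modality infraslow band power per subject × state, with contrasts."""
    log.info("power analysis: run %s, %d subjects", cfg.run_id(), cfg.n_subjects)
    grid = FreqGrid()
    rows, spec_rows = [], []
    for sid, rec in _subject_recordings(cfg):
        vox_rng = np.random.default_rng((cfg.seed, hash(sid) & 0x7FFFFFFF))
        vox_idx = subsample_voxels(rec.mask, cfg.subsample_fraction, vox_rng)
        flat_bold = rec.bold.reshape(-1, rec.n_samples)[vox_idx]
        signals = {"bold": flat_bold, "eeg": rec.eeg, "nirs_h2o": rec.nirs[2]}
        epochs = extract_state_epochs(rec.hypnogram, signals, rec.fs,
                                      cfg.epoch_len_s,
                                      n_per_state=cfg.epochs_per_state,
                                      subject_id=sid)
        for ep in epochs:
            for mod in modalities:
                tf = tf_power(ep.signals[mod], grid, rec.fs)
                mean_curve = tf.power.mean(axis=-1)
                if mean_curve.ndim > 1:           # average channels/voxels
                    mean_curve = mean_curve.mean(axis=0)
                tf.power = mean_curve[:, None]
                bp = band_power(tf, cfg.band).value
                rows.append({"subject": sid, "state": ep.state,
                             "modality": mod, "band_power": bp})
                spec_rows.append({"subject": sid, "state": ep.state, "modality": mod,
                                  **{f"f_{i + 1}": mean_curve[i] for i in range(mean_curve.size)}})
    band_df = (pd.DataFrame(rows)
               .groupby(["subject", "state", "modality"], as_index=False)
               .mean())
    states = [s for s in cfg.synthetic.states if s in set(band_df["state"])] \
        if cfg.input_dirs is None else sorted(set(band_df["state"]))
    c_rows = []
    for mod in modalities:
        sub = band_df[band_df["modality"] == mod]
        for s1, s2 in _state_contrast_pairs(states):
            a = sub.loc[sub["state"] == s1, "band_power"].to_numpy()
            b = sub.loc[sub["state"] == s2, "band_power"].to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            gc = wilcoxon_ranksum(a, b)
            c_rows.append({"modality": mod, "contrast": f"{s1}-{s2}",
                           "z": gc.z, "p": gc.p, "n1": gc.n1, "n2": gc.n2,
                           "median_1": float(np.median(a)), "median_2": float(np.median(b))})
    contrasts = pd.DataFrame(c_rows)
    if len(contrasts):
        contrasts["p_adj"] = fdr_adjust(contrasts["p"].to_numpy())
    result = PowerResult(band_powers=band_df, spectra=pd.DataFrame(spec_rows),
                         contrasts=contrasts)
    if cfg.out_dir:
        result.out_dir = _write_power_outputs(cfg, result)
    return result


def run_coupling_analysis(cfg: RunConfig) -> CouplingResult:
    """TE maps, aggregates, state contrasts, and the lag-map control."""
    log.info("coupling analysis: run %s, %d subjects", cfg.run_id(), cfg.n_subjects)
    fir = FilterSpec(order=cfg.fir_order, band=cfg.band, fs=cfg.synthetic.fs)
    lag = default_lag(cfg.f_center, cfg.synthetic.fs)
    agg_rows = []
    delta_maps: dict[tuple[str, str], list[np.ndarray]] = {}
    electrode_rows = []
    lag_rows = []
    mask = atlas = None
    rng_master = np.random.default_rng(cfg.seed)
    for sid, rec in _subject_recordings(cfg):
        try:
            mask, atlas = rec.mask, rec.atlas
            vox = filter_band(rec.bold[mask], fir)
            eeg = filter_band(rec.eeg, fir)
            h2o = filter_band(rec.nirs[2], fir)
            signals = {"bold": vox, "eeg": eeg, "h2o": h2o}
            epochs = extract_state_epochs(rec.hypnogram, signals, rec.fs,
                                          cfg.epoch_len_s,
                                          n_per_state=cfg.epochs_per_state,
                                          subject_id=sid)
        except Exception as err:
            raise RuntimeError(f"[preprocess] subject {sid}: {err}") from err
        epoch_maps: dict[str, list] = {}
        for ep in epochs:
            try:
                vol = np.zeros(mask.shape + (ep.signals["bold"].shape[-1],))
                vol[mask] = ep.signals["bold"]
                temap = pairwise_te_map(vol, mask, ep.signals["eeg"], ep.signals["h2o"],
                                        fs=rec.fs, n_bins=cfg.n_bins, lag=lag,
                                        band=cfg.band)
            except Exception as err:
                raise RuntimeError(f"[coupling] subject {sid} state {ep.state}: {err}") from err
            epoch_maps.setdefault(ep.state, []).append(temap)
        # epoch-level TE averaged within subject x state before group stats
        per_state_maps: dict[str, object] = {}
        for state, maps in epoch_maps.items():
            temap = maps[0]
            if len(maps) > 1:
                for field_ in ("delta", "te_xy", "te_yx"):
                    merged = {k: np.mean([getattr(m, field_)[k] for m in maps], axis=0)
                              for k in getattr(temap, field_)}
                    setattr(temap, field_, merged)
            per_state_maps[state] = temap
            agg = aggregate_te(temap, atlas)
            agg.insert(0, "state", state)
            agg.insert(0, "subject", sid)
            agg_rows.append(agg)
            for pair in ("bold_eeg", "bold_h2o"):
                delta_maps.setdefault((pair, state), []).append(temap.delta[pair])
            for e, d in enumerate(temap.delta["eeg_h2o"]):
                electrode_rows.append({"subject": sid, "state": state,
                                       "electrode": e + 1, "delta_te": float(d)})
        # lag-map control on the first available state's epoch
        if per_state_maps:
            st0 = next(iter(per_state_maps))
            ep0 = next(e for e in epochs if e.state == st0)
            vol = np.zeros(mask.shape + (ep0.signals["bold"].shape[-1],))
            vol[mask] = ep0.signals["bold"]
            seed_mask = mask & (atlas == FRONTAL_LABEL)
            res = xcorr_lag_map(vol, mask, seed_mask, fs=rec.fs, f_center=cfg.f_center,
                                te_map=per_state_maps[st0].delta["bold_eeg"],
                                n_perm=min(cfg.n_perm, 1000),
                                rng=np.random.default_rng(rng_master.integers(2 ** 31)))
            lag_rows.append({"subject": sid, "state": st0, "rho": res.rho,
                             "p_perm": res.p_perm})
    aggregates = pd.concat(agg_rows, ignore_index=True)
    states = [s for s in dict.fromkeys(aggregates["state"])]

    c_rows = []
    for pair, region in [("bold_eeg", "whole_brain"), ("bold_h2o", "whole_brain"),
                         ("eeg_h2o", "electrodes")]:
        sub = aggregates[(aggregates["pair"] == pair) & (aggregates["region"] == region)]
        for s1, s2 in _state_contrast_pairs(states):
            a = sub.loc[sub["state"] == s1, "delta_te"].to_numpy()
            b = sub.loc[sub["state"] == s2, "delta_te"].to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            gc = wilcoxon_ranksum(a, b)
            c_rows.append({"pair": pair, "region": region, "contrast": f"{s1}-{s2}",
                           "z": gc.z, "p": gc.p, "n1": gc.n1, "n2": gc.n2,
                           "median_1": float(np.median(a)), "median_2": float(np.median(b))})
    roi_regions = sorted(set(aggregates["region"]) - {"whole_brain", "electrodes"})
    for pair in ("bold_eeg", "bold_h2o"):
        for region in roi_regions:
            sub = aggregates[(aggregates["pair"] == pair) & (aggregates["region"] == region)]
            for s1, s2 in _state_contrast_pairs(states):
                a = sub.loc[sub["state"] == s1, "delta_te"].to_numpy()
                b = sub.loc[sub["state"] == s2, "delta_te"].to_numpy()
                if a.size == 0 or b.size == 0:
                    continue
                gc = wilcoxon_ranksum(a, b)
                c_rows.append({"pair": pair, "region": region, "contrast": f"{s1}-{s2}",
                               "z": gc.z, "p": gc.p, "n1": gc.n1, "n2": gc.n2,
                               "median_1": float(np.median(a)), "median_2": float(np.median(b))})
    contrasts = pd.DataFrame(c_rows)
    if len(contrasts):
        contrasts["p_adj"] = fdr_adjust(contrasts["p"].to_numpy())

    voxelwise = {}
    stacked = {k: np.stack(v) for k, v in delta_maps.items()}
    for pair in ("bold_eeg", "bold_h2o"):
        for s1, s2 in _state_contrast_pairs(states):
            ka, kb = (pair, s1), (pair, s2)
            if ka not in stacked or kb not in stacked:
                continue
            if stacked[ka].shape[0] < 2 or stacked[kb].shape[0] < 2:
                continue
            A = np.nan_to_num(stacked[ka])
            B = np.nan_to_num(stacked[kb])
            voxelwise[(pair, f"{s1}-{s2}")] = permutation_test(
                A, B, mask=mask, n_perm=cfg.n_perm, params=cfg.tfce,
                rng=np.random.default_rng(rng_master.integers(2 ** 31)))

    result = CouplingResult(
        aggregates=aggregates, contrasts=contrasts, voxelwise=voxelwise,
        delta_maps=stacked, lag_control=pd.DataFrame(lag_rows),
        electrodes=pd.DataFrame(electrode_rows), mask=mask)
    if cfg.out_dir:
        result.out_dir = _write_coupling_outputs(cfg, result)
    return result


def generate_fixtures(cfg: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write one fixture directory per synthetic subject; returns the paths."""
    out = Path(out_dir)
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(2 ** 31, size=cfg.n_subjects)
    paths = []
    for i, s in enumerate(seeds):
        rec = generate_subject(cfg.synthetic, int(s))
        d = out / f"sub-{i + 1:02d}"
        fixture_io.write_fixture(rec, d)
        paths.append(d)
    return paths


# ---------------------------------------------------------------- outputs

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, files: list[Path]) -> None:
    manifest = {
        "run_id": cfg.run_id(),
        "seed": cfg.seed,
        "config": cfg.to_jsonable(),
        "outputs": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))


def _write_power_outputs(cfg: RunConfig, res: PowerResult) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in [("band_powers.tsv", res.band_powers),
                     ("spectra.tsv", res.spectra),
                     ("power_contrasts.tsv", res.contrasts)]:
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        files.append(p)
    summary = {
        "run_id": cfg.run_id(), "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "band": list(cfg.band),
        "median_band_power": {
            f"{mod}/{st}": float(np.median(g["band_power"]))
            for (mod, st), g in res.band_powers.groupby(["modality", "state"])},
    }
    p = out / "power_summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    files.append(p)
    _write_quicklook_power(out, res)
    _write_manifest(out, cfg, files)
    return out


def _write_coupling_outputs(cfg: RunConfig, res: CouplingResult) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in [("te_aggregates.tsv", res.aggregates),
                     ("te_contrasts.tsv", res.contrasts),
                     ("electrode_topography.tsv", res.electrodes),
                     ("lag_control.tsv", res.lag_control)]:
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        files.append(p)
    aff = np.eye(4)
    for (pair, state), maps in res.delta_maps.items():
        p = out / f"delta_te_{pair}_{state}_median.nii"
        nib.save(nib.Nifti1Image(np.nanmedian(maps, axis=0), aff), p)
        files.append(p)
    for (pair, contrast), perm in res.voxelwise.items():
        p = out / f"pmap_{pair}_{contrast}.nii"
        nib.save(nib.Nifti1Image(perm.p_map.astype(np.float64), aff), p)
        files.append(p)
    wb = res.aggregates[res.aggregates["region"] == "whole_brain"]
    summary = {
        "run_id": cfg.run_id(), "seed": cfg.seed,
        "lag_samples": default_lag(cfg.f_center, cfg.synthetic.fs),
        "whole_brain_median_delta_te": {
            f"{pair}/{st}": float(np.median(g["delta_te"]))
            for (pair, st), g in wb.groupby(["pair", "state"])},
        "voxelwise_significant_fraction": {
            f"{pair}/{contrast}": float(np.nanmean(perm.p_map[res.mask] < 0.05))
            for (pair, contrast), perm in res.voxelwise.items()},
    }
    p = out / "coupling_summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    files.append(p)
    _write_manifest(out, cfg, files)
    return out


def _write_quicklook_power(out: Path, res: PowerResult) -> None:
    """PNG quick-look of band power by state; figures stay out of the manifest."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    mods = sorted(set(res.band_powers["modality"]))
    fig, axes = plt.subplots(1, len(mods), figsize=(4 * len(mods), 3), squeeze=False)
    for ax, mod in zip(axes[0], mods):
        sub = res.band_powers[res.band_powers["modality"] == mod]
        states = list(dict.fromkeys(sub["state"]))
        data = [sub.loc[sub["state"] == s, "band_power"] for s in states]
        ax.boxplot(data, tick_labels=states)
        ax.set_title(mod)
        ax.set_ylabel("infraslow band power")
    fig.tight_layout()
    fig.savefig(fig_dir / "band_power.png", dpi=100)
    plt.close(fig)
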
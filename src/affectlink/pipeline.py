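"""End-to-end orchestration: dataset I/O, feature tables, CCA, RSA.

Feature tables are keyed by ``(subject, clip, window_start_s)`` so the
heavily overlapping 15 s / 1 s-hop analysis windows are first-class
rows.  ``run_all`` executes the full analysis on synthetic or on-disk
data: cue extraction per modality, per-subject CCA for the three
modality pairs (AV-EEG, AV-Face, EEG-Face), behaviour correlation, and
an optional network-representation comparison; results and a manifest
(config hash, seed, version) are written to the output directory, and
a stage whose output already exists under the same config hash is
reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audiocues import AUDIO_CUE_NAMES, extract_audio_cues
from .cca import (aggregate_loadings, cca_fit, fit_per_subject,
                  project_and_correlate, regress_emotions, standardize,
                  top_loadings)
from .eegfeat import (band_psd, clean_eeg, conditional_entropy_matrix,
                      entropy_feature_names, psd_feature_names, window_epochs)
from .facefeat import FACE_CUE_NAMES, compute_face_cues, fuse_frames
from .rsa import NetworkConfig, build_network, eeg_to_topo_image, similarity_matrix
from .synthdata import LinkageConfig, gen_dataset, render_face
from .types import (AudioClip, BehaviorLabels, EEGEpoch, FrameSequence,
                    LandmarkSequence, LandmarkSet, LatentAffect, StimulusClip,
                    SynthTrial)
from .visualcues import VISUAL_CUE_NAMES, extract_visual_cues

__all__ = ["RunConfig", "run_all", "build_feature_tables", "write_dataset",
           "load_dataset", "linkage_experiment"]

log = logging.getLogger(__name__)

AV_CUE_NAMES: tuple[str, ...] = tuple(AUDIO_CUE_NAMES) + tuple(VISUAL_CUE_NAMES)
KEY_COLS = ["subject", "clip", "window_start_s"]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    seed: int = 0
    # synthetic cohort
    n_subjects: int = 3
    n_clips: int = 6
    clip_seconds: float = 35.0
    snr: float | None = 2.0
    label_noise_sd: float = 0.5
    # windowing
    win_s: float = 15.0
    hop_s: float = 1.0
    # generator scale (desk-scale defaults; see docs/methods.md)
    eeg_fs: float = 256.0
    n_channels: int = 32
    fps: float = 4.0
    frame_size: tuple[int, int] = (64, 64)
    audio_fs: float = 8000.0
    # features
    clean: bool = True
    include_entropy: bool = True
    entropy_bins: int = 16
    audio_hop_ms: float = 10.0
    # CCA
    n_components: int = 3
    ridge: float = 1e-3
    # RSA
    run_rsa: bool = False
    rsa_inputs: int = 50
    rsa_image_side: int = 32

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_size"] = list(d["frame_size"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "frame_size" in raw:
            raw["frame_size"] = tuple(raw["frame_size"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def linkage(self) -> LinkageConfig:
        return LinkageConfig(snr=self.snr, label_noise_sd=self.label_noise_sd)


# --------------------------------------------------------------------------
# dataset I/O (the `affectlink synth` on-disk layout)
# --------------------------------------------------------------------------

def write_dataset(trials: list[SynthTrial], out_dir: str | Path) -> None:
    """WAV audio, PNG frames, HDF5 EEG + landmarks, CSV labels, JSON manifest."""
    import h5py
    import imageio.v3 as iio
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in trials:
        tdir = out / f"s{t.subject:02d}_c{t.clip:03d}"
        (tdir / "frames").mkdir(parents=True, exist_ok=True)
        wavfile.write(tdir / "audio.wav", int(t.stimulus.audio.fs),
                      (np.clip(t.stimulus.audio.samples, -1, 1) * 32767).astype(np.int16))
        for i, frame in enumerate(t.stimulus.frames.frames):
            iio.imwrite(tdir / "frames" / f"f{i:05d}.png", frame)
        with h5py.File(tdir / "eeg.h5", "w") as f:
            f.create_dataset("data", data=t.eeg.data)
            f.attrs["fs"] = t.eeg.fs
            f.create_dataset("channel_names",
                             data=np.array(t.eeg.channel_names, dtype="S"))
            f.create_dataset("channel_xy", data=t.eeg.channel_xy)
        with h5py.File(tdir / "landmarks.h5", "w") as f:
            f.create_dataset("points", data=t.landmarks.points)
            f.attrs["face_box"] = t.landmarks.face_box
            f.attrs["fps"] = t.stimulus.frames.fps
        rows.append({"subject": t.subject, "clip": t.clip,
                     "valence": t.labels.valence, "arousal": t.labels.arousal,
                     "emotion": t.labels.emotion,
                     "z_valence": t.latent.z_valence, "z_arousal": t.latent.z_arousal})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    manifest = {"version": __version__, "n_trials": len(trials),
                "seed": trials[0].seed if trials else None,
                "knob_ground_truth": {f"s{t.subject}_c{t.clip}": t.knobs for t in trials}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(data_dir: str | Path) -> list[SynthTrial]:
    """Load a dataset written by :func:`write_dataset`."""
    import h5py
    import imageio.v3 as iio
    from scipy.io import wavfile

    root = Path(data_dir)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing labels file: {labels_path}")
    labels = pd.read_csv(labels_path)
    trials = []
    for _, row in labels.iterrows():
        tdir = root / f"s{int(row['subject']):02d}_c{int(row['clip']):03d}"
        fs_wav, wav = wavfile.read(tdir / "audio.wav")
        if np.issubdtype(wav.dtype, np.integer):
            wav = wav.astype(np.float64) / np.iinfo(wav.dtype).max
        audio = AudioClip(samples=np.asarray(wav, dtype=np.float64), fs=float(fs_wav))
        frame_files = sorted((tdir / "frames").glob("*.png"))
        with h5py.File(tdir / "landmarks.h5", "r") as f:
            lms = LandmarkSequence(points=f["points"][()],
                                   face_box=tuple(f.attrs["face_box"]))
            fps = float(f.attrs["fps"])
        frames = FrameSequence(
            frames=np.stack([iio.imread(p) for p in frame_files]), fps=fps)
        with h5py.File(tdir / "eeg.h5", "r") as f:
            eeg = EEGEpoch(data=f["data"][()], fs=float(f.attrs["fs"]),
                           channel_names=[n.decode() for n in f["channel_names"][()]],
                           channel_xy=f["channel_xy"][()])
        trials.append(SynthTrial(
            subject=int(row["subject"]), clip=int(row["clip"]),
            stimulus=StimulusClip(audio=audio, frames=frames), eeg=eeg,
            landmarks=lms,
            labels=BehaviorLabels(int(row["valence"]), int(row["arousal"]),
                                  row["emotion"]),
            latent=LatentAffect(float(row["z_valence"]), float(row["z_arousal"])),
            seed=0))
    return trials


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

def _window_starts(duration: float, win_s: float, hop_s: float) -> np.ndarray:
    count = int(np.floor((duration - win_s) / hop_s)) + 1
    return hop_s * np.arange(max(count, 0))


def _slice_stimulus(trial: SynthTrial, t0: float, win_s: float) -> StimulusClip:
    fr = trial.stimulus.frames
    i0 = int(round(t0 * fr.fps))
    i1 = max(int(round((t0 + win_s) * fr.fps)), i0 + 2)
    au = trial.stimulus.audio
    s0, s1 = int(round(t0 * au.fs)), int(round((t0 + win_s) * au.fs))
    return StimulusClip(audio=AudioClip(au.samples[s0:s1], au.fs),
                        frames=FrameSequence(fr.frames[i0:i1], fr.fps))


def _window_landmarks(trial: SynthTrial, t0: float, win_s: float) -> LandmarkSet:
    fps = trial.stimulus.frames.fps
    i0 = int(round(t0 * fps))
    i1 = max(int(round((t0 + win_s) * fps)), i0 + 1)
    seg = LandmarkSequence(points=trial.landmarks.points[i0:i1],
                           face_box=trial.landmarks.face_box)
    return seg.mean_landmarks()


def build_feature_tables(trials: list[SynthTrial], config: RunConfig,
                         ) -> dict[str, pd.DataFrame]:
    """Per-window AV / EEG / Face cue tables plus aligned labels."""
    av_rows, eeg_rows, face_rows, label_rows = [], [], [], []
    eeg_names = None
    for trial in trials:
        eeg = clean_eeg(trial.eeg) if config.clean else trial.eeg
        windows = window_epochs(eeg, config.win_s, config.hop_s)
        starts = _window_starts(eeg.duration, config.win_s, config.hop_s)
        if eeg_names is None:
            eeg_names = psd_feature_names(eeg.channel_names)
            if config.include_entropy:
                eeg_names += entropy_feature_names(eeg.channel_names)
        for t0, win in zip(starts, windows):
            key = {"subject": trial.subject, "clip": trial.clip,
                   "window_start_s": float(t0)}
            stim = _slice_stimulus(trial, t0, config.win_s)
            audio = extract_audio_cues(stim.audio, mfcc_hop_ms=config.audio_hop_ms)
            visual = extract_visual_cues(stim.frames)
            av_rows.append({**key, **dict(zip(
                AV_CUE_NAMES, np.concatenate([audio.as_array(), visual.as_array()])))})
            feats = band_psd(win)
            if config.include_entropy:
                feats = np.concatenate([
                    feats, conditional_entropy_matrix(win, bins=config.entropy_bins)])
            eeg_rows.append({**key, **dict(zip(eeg_names, feats))})
            face = compute_face_cues(_window_landmarks(trial, t0, config.win_s))
            face_rows.append({**key, **dict(zip(FACE_CUE_NAMES, face.as_array()))})
            label_rows.append({**key, "valence": trial.labels.valence,
                               "arousal": trial.labels.arousal,
                               "emotion": trial.labels.emotion})
    return {"av": pd.DataFrame(av_rows), "eeg": pd.DataFrame(eeg_rows),
            "face": pd.DataFrame(face_rows), "labels": pd.DataFrame(label_rows)}


def _impute(df: pd.DataFrame) -> pd.DataFrame:
    """Column-mean imputation (documented) for any missing cue values."""
    feat = df.drop(columns=KEY_COLS)
    if feat.isna().any().any():
        log.warning("imputing %d missing values with column means",
                    int(feat.isna().sum().sum()))
        feat = feat.fillna(feat.mean())
    return pd.concat([df[KEY_COLS], feat], axis=1)


# --------------------------------------------------------------------------
# analysis
# --------------------------------------------------------------------------

def _pair_analysis(tables: dict[str, pd.DataFrame], name_x: str, name_y: str,
                   config: RunConfig) -> dict:
    dfx, dfy = _impute(tables[name_x]), _impute(tables[name_y])
    labels = tables["labels"]
    zx, names_x = standardize(dfx.drop(columns=KEY_COLS).to_numpy(),
                              list(dfx.columns[len(KEY_COLS):]))
    zy, names_y = standardize(dfy.drop(columns=KEY_COLS).to_numpy(),
                              list(dfy.columns[len(KEY_COLS):]))
    k = min(config.n_components, zx.shape[1], zy.shape[1])
    pooled = cca_fit(zx, zy, n_components=k, ridge=config.ridge,
                     x_names=names_x, y_names=names_y)
    subjects = dfx["subject"].to_numpy()
    per_subject = {}
    if len(np.unique(subjects)) > 1:
        fits = fit_per_subject(zx, zy, subjects, n_components=k,
                               ridge=config.ridge, x_names=names_x, y_names=names_y)
        for side, names in (("x", names_x), ("y", names_y)):
            agg = aggregate_loadings(fits, side=side)
            order = np.argsort(-agg, kind="stable")[:10]
            per_subject[side] = [(names[i], float(agg[i])) for i in order]
    behavior = project_and_correlate(pooled, zx, zy,
                                     labels["valence"].to_numpy(),
                                     labels["arousal"].to_numpy())
    ux, _ = pooled.variates(zx, zy)
    emotions = regress_emotions(ux[:, 0], labels["emotion"].to_numpy())
    return {
        "pair": f"{name_x}-{name_y}",
        "canonical_correlations": [float(c) for c in pooled.canonical_correlations],
        "top_loadings_x": top_loadings(pooled, "x", min(10, len(names_x))),
        "top_loadings_y": top_loadings(pooled, "y", min(10, len(names_y))),
        "subject_mean_loadings": per_subject,
        "behavior": behavior,
        "emotion_regression": emotions,
    }


def _rsa_stage(trials: list[SynthTrial], config: RunConfig) -> np.ndarray:
    """Topo-image and fused-face-image similarity matrix over sampled windows."""
    from skimage.transform import resize

    eeg_imgs, face_imgs = [], []
    for trial in trials:
        if len(eeg_imgs) >= config.rsa_inputs:
            break
        wins = window_epochs(trial.eeg, config.win_s, config.win_s)
        fps = trial.stimulus.frames.fps
        for k, win in enumerate(wins):
            if len(eeg_imgs) >= config.rsa_inputs:
                break
            eeg_imgs.append(eeg_to_topo_image(win, side=config.rsa_image_side).image)
            i0 = int(round(k * config.win_s * fps))
            pts = trial.landmarks.points[i0:i0 + max(int(config.win_s * fps), 1)]
            rendered = [render_face(p, trial.landmarks.face_box, image_size=(128, 128))
                        for p in pts[:3]]
            fused = fuse_frames(rendered)
            small = resize(fused / 255.0, (config.rsa_image_side,) * 2,
                           anti_aliasing=True)
            face_imgs.append(np.repeat(small[..., None], 3, axis=-1))
    if len(eeg_imgs) < 3:
        raise ValueError("need at least 3 input windows for the network comparison")
    seed = trials[0].seed if trials else 0
    net_a = build_network(NetworkConfig(input_side=config.rsa_image_side, seed=seed))
    net_b = build_network(NetworkConfig(input_side=config.rsa_image_side, seed=seed + 1))
    return similarity_matrix(net_a.forward(np.stack(eeg_imgs)),
                             net_b.forward(np.stack(face_imgs)), seed=seed)


# --------------------------------------------------------------------------
# run_all
# --------------------------------------------------------------------------

def run_all(config: RunConfig, out_dir: str | Path, *, synthetic: bool = True,
            data_dir: str | Path | None = None) -> dict:
    """Execute every stage; returns the result bundle it also writes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    if synthetic:
        trials = gen_dataset(config.n_subjects, config.n_clips, config.clip_seconds,
                             config.linkage(), config.seed, eeg_fs=config.eeg_fs,
                             n_channels=config.n_channels, fps=config.fps,
                             frame_size=config.frame_size, audio_fs=config.audio_fs)
    else:
        if data_dir is None:
            raise ValueError("data_dir required when synthetic=False")
        trials = load_dataset(data_dir)

    # stage: feature tables (reused when the config hash matches)
    manifest_path = out / "manifest.json"
    stale = True
    if manifest_path.exists():
        try:
            stale = json.loads(manifest_path.read_text()).get("config_hash") != chash
        except json.JSONDecodeError:
            stale = True
    table_paths = {k: out / f"features_{k}.csv" for k in ("av", "eeg", "face")}
    table_paths["labels"] = out / "labels.csv"
    if not stale and all(p.exists() for p in table_paths.values()):
        log.info("reusing feature tables for config hash %s", chash)
        tables = {k: pd.read_csv(p) for k, p in table_paths.items()}
    else:
        tables = build_feature_tables(trials, config)
        for k, p in table_paths.items():
            tables[k].to_csv(p, index=False)

    results = {"config_hash": chash, "seed": config.seed, "version": __version__,
               "n_windows": int(len(tables["labels"])), "pairs": {}}
    for name_x, name_y in (("av", "eeg"), ("av", "face"), ("eeg", "face")):
        pair = _pair_analysis(tables, name_x, name_y, config)
        results["pairs"][pair["pair"]] = pair
        (out / f"cca_{name_x}_{name_y}.json").write_text(json.dumps(pair, indent=2))

    if config.run_rsa:
        sim = _rsa_stage(trials, config)
        pd.DataFrame(sim).to_csv(out / "rsa_similarity.csv", index=False)
        results["rsa_similarity_shape"] = list(sim.shape)

    manifest = {"config_hash": chash, "config": config.to_dict(),
                "seed": config.seed, "version": __version__,
                "n_trials": len(trials), "n_windows": results["n_windows"]}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    (out / "results.json").write_text(json.dumps(results, indent=2))
    return results


# --------------------------------------------------------------------------
# planted-linkage experiment (texture <-> central beta)
# --------------------------------------------------------------------------

def linkage_experiment(n_windows: int = 1500, snr: float = 2.0, seed: int = 0, *,
                       eeg_fs: float = 128.0, frame_size: tuple[int, int] = (32, 32),
                       fps: float = 2.0 / 15.0, audio_hop_ms: float = 25.0,
                       ridge: float = 0.5) -> dict:
    """One seed of the texture <-> central-beta recovery experiment.

    Generates ``n_windows`` independent 15 s windows in which the
    *arousal* latent drives both the frame fine-texture knob and the
    central-channel beta amplitude (lighting and audio stay on the
    valence latent), extracts the 30 AV cues and 96 PSD features, fits
    CCA, and reports the top loading name on each side.  Reduced frame,
    rate and hop settings keep the experiment at desk scale; see
    docs/methods.md.
    """
    linkage = LinkageConfig(snr=snr, texture_latent="arousal",
                            lighting_latent="valence", audio_latent="valence",
                            beta_latent="arousal", face_latent="arousal")
    trials = gen_dataset(1, n_windows, 15.0, linkage, seed, eeg_fs=eeg_fs,
                         fps=fps, frame_size=frame_size, n_cuts=0)
    av = np.empty((n_windows, len(AV_CUE_NAMES)))
    psd = None
    for i, t in enumerate(trials):
        audio = extract_audio_cues(t.stimulus.audio, mfcc_hop_ms=audio_hop_ms,
                                   vad_hop_ms=50.0, pitch_hop_ms=100.0)
        visual = extract_visual_cues(t.stimulus.frames)
        av[i] = np.concatenate([audio.as_array(), visual.as_array()])
        feats = band_psd(t.eeg)
        if psd is None:
            psd = np.empty((n_windows, len(feats)))
            psd_names = psd_feature_names(t.eeg.channel_names)
        psd[i] = feats
    zx, names_x = standardize(av, list(AV_CUE_NAMES))
    zy, names_y = standardize(psd, psd_names)
    res = cca_fit(zx, zy, n_components=1, ridge=ridge,
                  x_names=names_x, y_names=names_y)
    top_av = top_loadings(res, "x", 3)
    top_eeg = top_loadings(res, "y", 3)
    central_beta = {f"psd_{ch}_beta" for ch in ("C3", "Cz", "C4")}
    return {
        "first_correlation": float(res.canonical_correlations[0]),
        "top_av": top_av,
        "top_eeg": top_eeg,
        "av_hit": top_av[0][0] == "glcm_homogeneity",
        "eeg_hit": top_eeg[0][0] in central_beta,
    }
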
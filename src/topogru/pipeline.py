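"""End-to-end pipeline: simulate|load → preprocess → brainmap → train/evaluate.

Every stage reads and writes an HDF5 container (plus EDF/CSV for raw
data) under the configured working directory, so a run can resume from
any stage.  Each artifact carries the SHA-256 hash of the fully-resolved
configuration that produced it; the resolved configuration itself is
written as YAML beside the outputs.

Normalisation of the brain maps is fold-aware: the z-scoring statistics
are computed on the training side of each split only and applied
unchanged to held-out data (see :class:`NormalizingModel`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import brainmap as bm
from . import evaluation as ev
from . import preprocessing as pp
from . import synthetic as syn
from .io import RawRecording, load_labels, load_montage, read_edf, save_labels, write_edf
from .model import CnnConfig, CnnGruModel, ModelConfig, TrainConfig

logger = logging.getLogger("topogru")

STAGES = ("simulate", "preprocess", "brainmap", "train", "evaluate")


@dataclass
class SegmentationConfig:
    win_seconds: float = 1.0
    max_segments: int = 10
    offset_seconds: float = 0.0


@dataclass
class BrainmapConfig:
    grid_size: int = 28
    frame_len: float = 0.5
    frame_step: float = 0.25
    fill: float = 0.0
    norm: str = "per_band_z"         # none | per_band_z | global_max
    sequence_scope: str = "frame"    # frame | segment


@dataclass
class IcaStageConfig:
    enabled: str = "auto"   # "auto": run only when artifacts are configured
    config: pp.IcaArtifactConfig = field(default_factory=pp.IcaArtifactConfig)


@dataclass
class NetConfig:
    conv_filters: tuple[int, ...] = (32,)
    hidden_size: int = 64
    dropout_rate: float = 0.5


@dataclass
class PipelineConfig:
    """Fully-resolved settings of one pipeline run."""

    cohort: syn.CohortSpec = field(default_factory=syn.CohortSpec)
    filter: pp.FilterSpec = field(default_factory=pp.FilterSpec)
    ica: IcaStageConfig = field(default_factory=IcaStageConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    brainmap: BrainmapConfig = field(default_factory=BrainmapConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: ev.SplitPlan = field(default_factory=ev.SplitPlan)
    repeats: int = 1
    seed: int = 0
    workdir: str = "topogru_run"

    def resolved(self) -> "PipelineConfig":
        """Propagate the top-level seed into stage seeds left at default."""
        out = replace(self)
        out.cohort = replace(self.cohort, seed=self.cohort.seed or self.seed)
        out.train = replace(self.train, seed=self.train.seed or self.seed)
        out.split = replace(self.split, seed=self.split.seed or self.seed)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["net"]["conv_filters"] = list(self.net.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw: dict = {}
        if "cohort" in d:
            c = dict(d.pop("cohort"))
            if "effect" in c:
                c["effect"] = syn.BandEffect(**c["effect"])
            if "artifact_cfg" in c:
                c["artifact_cfg"] = syn.ArtifactSpec(**c["artifact_cfg"])
            kw["cohort"] = syn.CohortSpec(**c)
        if "filter" in d:
            kw["filter"] = pp.FilterSpec(**d.pop("filter"))
        if "ica" in d:
            i = dict(d.pop("ica"))
            if "config" in i:
                i["config"] = pp.IcaArtifactConfig(**i["config"])
            kw["ica"] = IcaStageConfig(**i)
        if "segmentation" in d:
            kw["segmentation"] = SegmentationConfig(**d.pop("segmentation"))
        if "brainmap" in d:
            kw["brainmap"] = BrainmapConfig(**d.pop("brainmap"))
        if "net" in d:
            n = dict(d.pop("net"))
            n["conv_filters"] = tuple(n.get("conv_filters", (32,)))
            kw["net"] = NetConfig(**n)
        if "train" in d:
            kw["train"] = TrainConfig(**d.pop("train"))
        if "split" in d:
            kw["split"] = ev.SplitPlan(**d.pop("split"))
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("workdir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Feature building (shared by stages, tests, and the acceptance script)
# ---------------------------------------------------------------------------

def preprocess_recording(rec: RawRecording, cfg: PipelineConfig) -> list[pp.Segment]:
    """Filter chain + optional ICA + segmentation for one recording."""
    out = pp.bandlimit_filter(rec, cfg.filter)
    if cfg.filter.notch_freq < rec.fs / 2:
        out = pp.notch_filter(out, cfg.filter.notch_freq)
    else:
        logger.warning("%s: notch %.6g Hz at/above Nyquist; skipped",
                       rec.subject_id, cfg.filter.notch_freq)
    run_ica = (cfg.ica.enabled == "on"
               or (cfg.ica.enabled == "auto"
                   and not cfg.cohort.artifact_cfg.is_null))
    if run_ica:
        out, report = pp.remove_artifacts_fastica(out, cfg.ica.config)
        logger.info("%s: removed components %s", rec.subject_id, report.flagged)
    return pp.segment(out, cfg.segmentation.win_seconds,
                      cfg.segmentation.max_segments,
                      cfg.segmentation.offset_seconds)


def build_features(cohort: list[tuple[RawRecording, int]],
                   cfg: PipelineConfig) -> tuple[ev.SequenceDataset, ev.SequenceDataset]:
    """Cohort → (brain-map sequence dataset, band-power vector dataset).

    The band-power dataset carries the same frames as flat per-channel
    θ/α/β power vectors, for the map-free recurrent baseline.
    """
    montage = load_montage(cfg.cohort.montage_name)
    layout = bm.aep_project(montage)
    seqs, powers, labels, subjects = [], [], [], []
    scope = cfg.brainmap.sequence_scope
    for rec, label in cohort:
        segments = preprocess_recording(rec, cfg)
        if scope == "frame":
            for seg in segments:
                s = bm.make_sequence(seg, layout, cfg.brainmap.frame_len,
                                     cfg.brainmap.frame_step,
                                     grid_size=cfg.brainmap.grid_size,
                                     fill=cfg.brainmap.fill)
                seqs.append(s.frames)
                powers.append(_frame_band_powers(seg, cfg))
                labels.append(label)
                subjects.append(rec.subject_id)
        elif scope == "segment":
            frames = [bm.make_brainmap(seg, layout,
                                       grid_size=cfg.brainmap.grid_size,
                                       fill=cfg.brainmap.fill).grid
                      for seg in segments]
            seqs.append(np.stack(frames))
            powers.append(np.stack([
                np.concatenate([bm.band_power(seg, b) for b in bm.DEFAULT_BANDS])
                for seg in segments]))
            labels.append(label)
            subjects.append(rec.subject_id)
        else:
            raise ValueError(f"unknown sequence scope {scope!r}")
    mask = bm.hull_mask(layout, cfg.brainmap.grid_size)
    meta = {"config_hash": cfg.hash(), "sequence_scope": scope,
            "norm": cfg.brainmap.norm}
    X = np.stack(seqs)
    ds = ev.SequenceDataset(X, np.array(labels), np.array(subjects),
                            mask=mask, meta=meta)
    bp = ev.SequenceDataset(np.stack(powers), ds.y.copy(), ds.subjects.copy(),
                            meta=dict(meta, feature="bandpower"))
    return ds, bp


def _frame_band_powers(seg: pp.Segment, cfg: PipelineConfig) -> np.ndarray:
    win = int(round(cfg.brainmap.frame_len * seg.fs))
    step = max(1, int(round(cfg.brainmap.frame_step * seg.fs)))
    n_frames = (seg.n_samples - win) // step + 1
    rows = []
    for k in range(n_frames):
        sub = seg.data[:, k * step:k * step + win]
        rows.append(np.concatenate([
            bm.band_power(sub, b, fs=seg.fs) for b in bm.DEFAULT_BANDS]))
    return np.stack(rows)


class NormalizingModel:
    """Wrap a model so map normalisation uses training statistics only."""

    def __init__(self, base, mask: np.ndarray, mode: str):
        self.base = base
        self.mask = mask
        self.mode = mode
        self.stats: dict | None = None

    def fit(self, X, y):
        Xn, self.stats = bm.normalize_maps(X, self.mask, self.mode)
        self.base.fit(Xn, y)
        return self

    def predict(self, X):
        Xn, _ = bm.normalize_maps(X, self.mask, self.mode, stats=self.stats)
        return self.base.predict(Xn)

    def predict_proba(self, X):
        Xn, _ = bm.normalize_maps(X, self.mask, self.mode, stats=self.stats)
        return self.base.predict_proba(Xn)


def model_factory(cfg: PipelineConfig, dataset: ev.SequenceDataset):
    """Seed → normalising CNN-GRU classifier matching the pipeline config."""
    grid_shape = tuple(dataset.X.shape[2:])
    def make(seed: int):
        mcfg = ModelConfig(
            cnn=CnnConfig(input_shape=grid_shape,
                          conv_filters=tuple(cfg.net.conv_filters)),
            hidden_size=cfg.net.hidden_size,
            dropout_rate=cfg.net.dropout_rate)
        base = CnnGruModel(mcfg, seed=seed,
                           train_config=replace(cfg.train, seed=seed))
        return NormalizingModel(base, dataset.mask, cfg.brainmap.norm)
    return make


# ---------------------------------------------------------------------------
# Stage containers
# ---------------------------------------------------------------------------

def _h5_write(path: Path, arrays: dict, attrs: dict) -> None:
    with h5py.File(path, "w") as f:
        for k, v in arrays.items():
            v = np.asarray(v)
            if v.dtype.kind in ("U", "O"):
                v = v.astype("S")
            f.create_dataset(k, data=v, track_times=False)
        for k, v in attrs.items():
            f.attrs[k] = v


def _paths(cfg: PipelineConfig) -> dict:
    wd = Path(cfg.workdir)
    return {"raw": wd / "raw", "pre": wd / "preprocessed.h5",
            "features": wd / "features.h5", "model": wd / "model.npz",
            "report": wd / "report.json", "config": wd / "config.yaml"}


def stage_simulate(cfg: PipelineConfig) -> list[tuple[RawRecording, int]]:
    """Generate the cohort; write per-subject EDFs, labels CSV, spec YAML."""
    p = _paths(cfg)
    p["raw"].mkdir(parents=True, exist_ok=True)
    cohort = syn.generate_cohort(cfg.cohort)
    labels = {}
    for rec, label in cohort:
        write_edf(rec, p["raw"] / f"{rec.subject_id}.edf")
        labels[rec.subject_id] = label
    save_labels(labels, p["raw"] / "labels.csv")
    with open(p["raw"] / "cohort.yaml", "w") as fh:
        yaml.safe_dump({"cohort": cfg.to_dict()["cohort"],
                        "config_hash": cfg.hash()}, fh, sort_keys=True)
    return cohort


def load_raw(cfg: PipelineConfig) -> list[tuple[RawRecording, int]]:
    p = _paths(cfg)
    labels = load_labels(p["raw"] / "labels.csv")
    cohort = []
    for sid in sorted(labels):
        rec = read_edf(p["raw"] / f"{sid}.edf")
        cohort.append((rec, labels[sid]))
    return cohort


def stage_preprocess(cfg: PipelineConfig) -> None:
    """Raw EDFs → cleaned fixed-length segments container."""
    p = _paths(cfg)
    cohort = load_raw(cfg)
    segs, subjects, labels, indices = [], [], [], []
    ch_names = None
    for rec, label in cohort:
        ch_names = rec.channel_names
        for seg in preprocess_recording(rec, cfg):
            segs.append(seg.data)
            subjects.append(seg.subject_id)
            labels.append(label)
            indices.append(seg.index)
    _h5_write(p["pre"],
              {"segments": np.stack(segs), "subjects": np.array(subjects),
               "labels": np.array(labels), "segment_index": np.array(indices),
               "channel_names": np.array(ch_names)},
              {"fs": cfg.cohort.fs, "config_hash": cfg.hash()})
    logger.info("preprocess: wrote %d segments to %s", len(segs), p["pre"])


def stage_brainmap(cfg: PipelineConfig) -> None:
    """Segments container → brain-map sequence features container."""
    p = _paths(cfg)
    with h5py.File(p["pre"]) as f:
        segs = f["segments"][()]
        subjects = f["subjects"][()].astype(str)
        labels = f["labels"][()]
        indices = f["segment_index"][()]
        names = list(f["channel_names"][()].astype(str))
        fs = float(f.attrs["fs"])
    montage = load_montage(cfg.cohort.montage_name)
    layout = bm.aep_project(montage)
    seqs, powers = [], []
    for data, sid, k in zip(segs, subjects, indices):
        seg = pp.Segment(data, fs, str(sid), int(k), names)
        seqs.append(bm.make_sequence(seg, layout, cfg.brainmap.frame_len,
                                     cfg.brainmap.frame_step,
                                     grid_size=cfg.brainmap.grid_size,
                                     fill=cfg.brainmap.fill).frames)
        powers.append(_frame_band_powers(seg, cfg))
    mask = bm.hull_mask(layout, cfg.brainmap.grid_size)
    _h5_write(p["features"],
              {"sequences": np.stack(seqs), "bandpower": np.stack(powers),
               "labels": labels, "subjects": subjects.astype("S"),
               "mask": mask},
              {"config_hash": cfg.hash(), "norm": cfg.brainmap.norm,
               "sequence_scope": cfg.brainmap.sequence_scope})
    logger.info("brainmap: wrote %d sequences to %s", len(seqs), p["features"])


def load_features(cfg: PipelineConfig) -> tuple[ev.SequenceDataset, ev.SequenceDataset]:
    p = _paths(cfg)
    with h5py.File(p["features"]) as f:
        X = f["sequences"][()]
        bpX = f["bandpower"][()]
        y = f["labels"][()]
        subjects = f["subjects"][()].astype(str)
        mask = f["mask"][()].astype(bool)
        meta = dict(f.attrs)
    ds = ev.SequenceDataset(X, y, subjects, mask=mask, meta=meta)
    bp = ev.SequenceDataset(bpX, y.copy(), subjects.copy(),
                            meta=dict(meta, feature="bandpower"))
    return ds, bp


def stage_train(cfg: PipelineConfig) -> CnnGruModel:
    """Fit one final model on all features; serialise weights + metadata."""
    p = _paths(cfg)
    ds, _ = load_features(cfg)
    make = model_factory(cfg, ds)
    wrapped = make(cfg.train.seed or cfg.seed)
    wrapped.fit(ds.X, ds.y)
    model = wrapped.base
    model.norm_stats = wrapped.stats or {}
    model.save(p["model"])
    logger.info("train: saved model to %s", p["model"])
    return model


def stage_evaluate(cfg: PipelineConfig) -> dict:
    """Split-plan evaluation (training per fold); write report.json."""
    p = _paths(cfg)
    ds, _ = load_features(cfg)
    make = model_factory(cfg, ds)
    report = ev.evaluate(make, ds, cfg.split, repeats=cfg.repeats,
                         seed=cfg.seed)
    out = {"metrics": report.as_dict(), "config_hash": cfg.hash(),
           "n_samples": len(ds), "split": asdict(cfg.split),
           "repeats": cfg.repeats}
    with open(p["report"], "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    logger.info("evaluate: AC=%.4f ± %.4f over %d fold(s)",
                report.AC, report.AC_std or 0.0, report.n_folds)
    return out


def recovery_study(elevation: float = 2.0, seeds=range(5),
                   n_subjects: int = 53, depressed_fraction: float = 24 / 53,
                   fs: float = 250.0, duration: float = 12.0,
                   epochs: int = 40, patience: int = 8) -> dict:
    """Parameter-recovery experiment on simulated cohorts.

    For each seed: simulate a cohort with posterior θ/α power elevated by
    ``elevation`` in the depressed group, build brain-map sequences,
    train the CNN-GRU on a subject-level 2:1 split, and score the held-out
    subjects.  Returns per-seed segment-level accuracy, subject-level
    majority-vote accuracy, and the held-out subject count (the
    clustering-aware binomial unit for chance bounds: segment predictions
    within one subject are strongly correlated).
    """
    out = {"segment_ac": [], "subject_ac": [], "test_subjects": 0}
    for seed in seeds:
        spec = syn.CohortSpec(
            n_subjects=n_subjects, depressed_fraction=depressed_fraction,
            fs=fs, duration=duration,
            effect=syn.BandEffect(theta=elevation, alpha=elevation),
            seed=seed)
        cfg = PipelineConfig(cohort=spec,
                             train=TrainConfig(epochs=epochs,
                                               patience=patience, seed=seed),
                             seed=seed)
        cohort = syn.generate_cohort(spec)
        ds, _ = build_features(cohort, cfg)
        plan = ev.SplitPlan("independent_2to1", "subject", seed=seed)
        tr, te = ev.split(ds, plan)[0]
        mdl = model_factory(cfg, ds)(seed)
        mdl.fit(ds.X[tr], ds.y[tr])
        pred = mdl.predict(ds.X[te])
        out["segment_ac"].append(float((pred == ds.y[te]).mean()))
        subs = ds.subjects[te]
        votes = [float(np.round(pred[subs == s].mean()) == ds.y[te][subs == s][0])
                 for s in np.unique(subs)]
        out["subject_ac"].append(float(np.mean(votes)))
        out["test_subjects"] += len(np.unique(subs))
    return out


def run_pipeline(cfg: PipelineConfig, from_stage: str = "simulate") -> dict:
    """Run the stage chain from ``from_stage`` onward; returns the report.

    Earlier stages' containers must already exist when resuming.  The
    resolved configuration is written beside the outputs and every
    container carries the configuration hash.
    """
    cfg = cfg.resolved()
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; choose from {STAGES}")
    Path(cfg.workdir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(_paths(cfg)["config"])
    start = STAGES.index(from_stage)
    timings = {}
    for name in STAGES[start:]:
        t0 = time.perf_counter()
        {"simulate": stage_simulate, "preprocess": stage_preprocess,
         "brainmap": stage_brainmap, "train": stage_train,
         "evaluate": stage_evaluate}[name](cfg)
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-10s %.2f s", name, timings[name])
    with open(_paths(cfg)["report"]) as fh:
        report = json.load(fh)
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    with open(_paths(cfg)["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
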
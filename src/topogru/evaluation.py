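"""Metrics, validation protocols, and the baseline ladder.

Metrics are the four standard proportions computed from the confusion
counts of the depressed-vs-control decision:

    AC = (TP+TN)/(TP+FN+TN+FP)      SE = TP/(TP+FN)
    SP = TN/(FP+TN)                 F1 = 2·TP/(2·TP+FP+FN)

A metric with a zero denominator is reported as *undefined* (NaN plus a
warning), never silently 0.

Splits come in two modes (a single randomised 2:1 train/test split, and
leave-one-out cross-validation) × two units (segment, subject).  The
subject unit keeps every segment of a subject on one side of the boundary
and is the default: segment-level splitting lets segments of one person
appear in both train and test, which inflates accuracy on small cohorts.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (CnnConfig, CnnGruModel, ModelConfig, TrainConfig,
                    count_parameters)

logger = logging.getLogger("topogru")


@dataclass
class ConfusionCounts:
    """TP/FN/FP/TN of a binary depressed-vs-control decision."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass
class MetricsReport:
    """AC/SE/SP/F1, optionally with dispersion across folds or repeats."""

    AC: float
    SE: float
    SP: float
    F1: float
    AC_std: float | None = None
    SE_std: float | None = None
    SP_std: float | None = None
    F1_std: float | None = None
    n_folds: int = 1
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("AC", "SE", "SP", "F1", "AC_std", "SE_std", "SP_std",
                 "F1_std", "n_folds")}


@dataclass
class SplitPlan:
    """How to divide samples into train and test."""

    mode: str = "independent_2to1"   # or "loocv"
    unit: str = "subject"            # or "segment"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("independent_2to1", "loocv"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.unit not in ("subject", "segment"):
            raise ValueError(f"unknown split unit {self.unit!r}")


@dataclass
class SequenceDataset:
    """Labelled brain-map sequences with subject provenance.

    ``X`` is (n, T, grid, grid, 3) (or (n, T, D) for vector features),
    ``y`` the 0/1 labels (1 = depressed), ``subjects`` the subject id of
    every sample.
    """

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("X, y, subjects must have equal length")

    def __len__(self) -> int:
        return len(self.y)


def confusion(labels, predictions, positive=1) -> ConfusionCounts:
    """Tally TP/FN/FP/TN with ``positive`` marking the depressed class."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    pos = labels == positive
    pred_pos = predictions == positive
    return ConfusionCounts(
        TP=int(np.sum(pos & pred_pos)),
        FN=int(np.sum(pos & ~pred_pos)),
        FP=int(np.sum(~pos & pred_pos)),
        TN=int(np.sum(~pos & ~pred_pos)),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        undefined.append(name)
        return float("nan")
    return num / den


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """AC/SE/SP/F1 from confusion counts (NaN + warning when undefined)."""
    undefined: list[str] = []
    ac = _ratio(cc.TP + cc.TN, cc.n, "AC", undefined)
    se = _ratio(cc.TP, cc.TP + cc.FN, "SE", undefined)
    sp = _ratio(cc.TN, cc.FP + cc.TN, "SP", undefined)
    f1 = _ratio(2 * cc.TP, 2 * cc.TP + cc.FP + cc.FN, "F1", undefined)
    return MetricsReport(ac, se, sp, f1, undefined=tuple(undefined))


def split(dataset: SequenceDataset, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index folds per the plan: list of (train_idx, test_idx).

    ``independent_2to1`` returns one pair with |train| = round(2n/3) of
    the chosen units; ``loocv`` returns one fold per unit.  In subject
    mode all segments of a subject stay on one side.
    """
    n = len(dataset)
    rng = np.random.default_rng(plan.seed)
    if plan.unit == "segment":
        units = np.arange(n)
        groups = {i: np.array([i]) for i in units}
    else:
        uniq = np.unique(dataset.subjects)
        units = uniq
        groups = {u: np.nonzero(dataset.subjects == u)[0] for u in uniq}

    def expand(unit_sel) -> np.ndarray:
        idx = np.concatenate([groups[u] for u in unit_sel]) if len(unit_sel) \
            else np.array([], dtype=int)
        return np.sort(idx)

    if plan.mode == "independent_2to1":
        if len(units) < 3:
            raise ValueError("need at least 3 units for a 2:1 split")
        perm = rng.permutation(units)
        n_train = int(round(2 * len(units) / 3))
        return [(expand(perm[:n_train]), expand(perm[n_train:]))]
    # loocv
    if len(units) < 2:
        raise ValueError("need at least 2 units for LOOCV")
    folds = []
    for u in units:
        rest = np.array([v for v in units if v != u])
        folds.append((expand(rest), expand([u])))
    return folds


def evaluate(model_factory, dataset: SequenceDataset, plan: SplitPlan,
             repeats: int = 1, seed: int = 0) -> MetricsReport:
    """Train/test per fold (and repeat), aggregate mean ± std of metrics.

    ``model_factory(seed)`` must return an object with ``fit(X, y)`` and
    ``predict(X)``.  Each fold contributes one confusion table; the report
    carries the mean and standard deviation of each metric across
    folds × repeats.  Deterministic given ``seed``.
    """
    per_fold: list[MetricsReport] = []
    for rep in range(repeats):
        rep_plan = SplitPlan(plan.mode, plan.unit, plan.seed + rep)
        for fi, (tr, te) in enumerate(split(dataset, rep_plan)):
            mdl = model_factory(seed + 1000 * rep + fi)
            mdl.fit(dataset.X[tr], dataset.y[tr])
            preds = mdl.predict(dataset.X[te])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_fold.append(compute_metrics(confusion(dataset.y[te], preds)))
    def agg(name: str):
        vals = np.array([getattr(m, name) for m in per_fold])
        ok = vals[~np.isnan(vals)]
        if not len(ok):
            return float("nan"), float("nan")
        return float(ok.mean()), float(ok.std())
    (ac, ac_s), (se, se_s), (sp, sp_s), (f1, f1_s) = (
        agg("AC"), agg("SE"), agg("SP"), agg("F1"))
    return MetricsReport(ac, se, sp, f1, ac_s, se_s, sp_s, f1_s,
                         n_folds=len(per_fold))


# ---------------------------------------------------------------------------
# Baseline ladder
# ---------------------------------------------------------------------------

class SvmFlatModel:
    """RBF-kernel SVM on flattened, standardised brain maps.

    Frames are averaged over the sequence axis before flattening; decision
    ties (decision value exactly 0) break toward the control class.
    """

    def __init__(self, seed: int = 0):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        self._pipe = make_pipeline(StandardScaler(),
                                   SVC(kernel="rbf", random_state=seed))

    @staticmethod
    def _flatten(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X.mean(axis=1).reshape(len(X), -1)

    def fit(self, X, y):
        self._pipe.fit(self._flatten(X), y)
        return self

    def predict(self, X):
        dec = self._pipe.decision_function(self._flatten(X))
        return (dec > 0).astype(int)


def _neural_factory(variant: str, grid_shape, train_cfg: TrainConfig,
                    conv_filters=(32,), hidden_size: int = 64):
    """Factory of the neural baselines sharing one training protocol."""
    def make(seed: int):
        if variant == "cnn_gru":
            cfg = ModelConfig(cnn=CnnConfig(input_shape=grid_shape,
                                            conv_filters=tuple(conv_filters)),
                              hidden_size=hidden_size)
        elif variant == "cnn_only":
            cfg = ModelConfig(cnn=CnnConfig(input_shape=grid_shape,
                                            conv_filters=tuple(conv_filters)),
                              use_gru=False)
        elif variant == "gru_only":
            cfg = ModelConfig(frontend="flat", flat_dim=grid_shape[0],
                              hidden_size=hidden_size)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        from dataclasses import replace
        return CnnGruModel(cfg, seed=seed,
                           train_config=replace(train_cfg, seed=seed))
    return make


def band_power_vectors(dataset: SequenceDataset,
                       channel_powers: np.ndarray) -> SequenceDataset:
    """Dataset view for the map-free GRU baseline.

    ``channel_powers`` is (n, T, 3·n_channels) per-frame band-power
    vectors produced by the feature stage alongside the maps.
    """
    return SequenceDataset(channel_powers, dataset.y, dataset.subjects,
                           meta=dict(dataset.meta, feature="bandpower"))


def benchmark(dataset: SequenceDataset, plan: SplitPlan,
              models: tuple[str, ...] = ("svm_flat", "cnn_only", "gru_only",
                                         "cnn_gru"),
              train_cfg: TrainConfig | None = None,
              bandpower_dataset: SequenceDataset | None = None,
              repeats: int = 1, seed: int = 0) -> list[dict]:
    """Model-comparison table: one row per model (metrics, params, time).

    ``gru_only`` runs on per-channel band-power vectors (no spatial map)
    and therefore needs ``bandpower_dataset``; it is skipped with a log
    message when that is absent.
    """
    train_cfg = train_cfg or TrainConfig()
    grid_shape = tuple(dataset.X.shape[2:])
    rows = []
    for name in models:
        if name == "svm_flat":
            factory = lambda s: SvmFlatModel(s)
            ds, n_params = dataset, None
        elif name == "gru_only":
            if bandpower_dataset is None:
                logger.warning("benchmark: no band-power features; "
                               "skipping gru_only")
                continue
            ds = bandpower_dataset
            factory = _neural_factory(name, (ds.X.shape[2],), train_cfg)
            n_params = count_parameters(factory(0))
        else:
            ds = dataset
            factory = _neural_factory(name, grid_shape, train_cfg)
            n_params = count_parameters(factory(0))
        t0 = time.perf_counter()
        report = evaluate(factory, ds, plan, repeats=repeats, seed=seed)
        rows.append({"model": name, "time_s": time.perf_counter() - t0,
                     "parameters": n_params, **report.as_dict()})
    return rows


def depth_sweep(dataset: SequenceDataset, plan: SplitPlan,
                depth_filters: tuple[tuple[int, ...], ...] = ((32,), (32, 32),
                                                              (32, 32, 32)),
                train_cfg: TrainConfig | None = None,
                repeats: int = 1, seed: int = 0) -> list[dict]:
    """Vary the number of convolution layers; report time/params/metrics.

    Filter counts per layer are configurable; only the 1-layer row has a
    canonical parameter count (3·3·3·32+32 = 896 for 3-channel input).
    """
    train_cfg = train_cfg or TrainConfig()
    grid_shape = tuple(dataset.X.shape[2:])
    rows = []
    for filters in depth_filters:
        factory = _neural_factory("cnn_gru", grid_shape, train_cfg,
                                  conv_filters=filters)
        probe = factory(0)
        t0 = time.perf_counter()
        report = evaluate(factory, dataset, plan, repeats=repeats, seed=seed)
        rows.append({
            "layers": len(filters),
            "time_s": time.perf_counter() - t0,
            "conv_parameters": count_parameters(probe, "conv_layer"),
            "total_parameters": count_parameters(probe),
            **report.as_dict(),
        })
    return rows


def format_table(rows: list[dict]) -> str:
    """Plain-text table of benchmark/depth-sweep rows."""
    if not rows:
        return "(empty)"
    keys = [k for k in rows[0] if not k.endswith("_std")]
    def fmt(v):
        if v is None:
            return "-"
        if isinstance(v, float):
            return f"{v:.4f}" if abs(v) < 10 else f"{v:.1f}"
        return str(v)
    widths = {k: max(len(k), *(len(fmt(r.get(k))) for r in rows)) for k in keys}
    head = "  ".join(k.ljust(widths[k]) for k in keys)
    lines = [head, "-" * len(head)]
    for r in rows:
        lines.append("  ".join(fmt(r.get(k)).ljust(widths[k]) for k in keys))
    return "\n".join(lines)
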
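"""Metrics, ROC/AUC, and the end-to-end pipeline with its sweeps.

``run_pipeline`` chains the whole method on a synthetic scenario:
generate -> (optionally corrupt and) clean -> window -> featurize -> split
65/15/20 -> cluster + calibrate + auto-label the unlabeled training windows
-> federated BiLSTM training on ground-truth plus propagated labels ->
evaluate on the held-out test split against the generator's ground truth.
The unlabeled-fraction sweep re-runs it over masking ratios (30% .. 99.9%)
and the feature sweep over feature-vector lengths (4 .. 45).

Metric conventions: macro averaging for the headline precision/recall/F1;
a class never predicted gets precision 0 (flagged); multiclass ROC is
one-vs-rest with trapezoid AUC, macro-averaged over classes that have both
positives and negatives in the truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autolabel, federated, ingest, neural, synthetic
from .ingest import Dataset, ValidationError

logger = logging.getLogger("fedhar")


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class and macro precision/recall/F1."""

    classes: list[str]
    confusion: np.ndarray  # (true, predicted) counts
    per_class: pd.DataFrame  # columns precision, recall, f1, support
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    zero_division_classes: list[str] = field(default_factory=list)


def compute_metrics(true_labels: list[str], predicted_labels: list[str]) -> MetricsReport:
    """Standard multiclass metrics; undefined ratios reported as 0 and flagged."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label lists must have equal length")
    if not true_labels:
        raise ValidationError("label lists are empty")
    classes = sorted(set(true_labels) | set(predicted_labels))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        cm[idx[t], idx[p]] += 1
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    flagged = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / np.maximum(pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.maximum(true_tot, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    for i, c in enumerate(classes):
        if pred_tot[i] == 0 or true_tot[i] == 0:
            flagged.append(c)
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": true_tot.astype(int),
        },
        index=classes,
    )
    return MetricsReport(
        classes=classes,
        confusion=cm,
        per_class=per_class,
        accuracy=float(tp.sum() / cm.sum()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        zero_division_classes=flagged,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    """One-vs-rest ROC points per class and the macro AUC."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auc_per_class: dict[str, float]
    macro_auc: float


def _binary_roc(scores: np.ndarray, positive: np.ndarray):
    """(fpr, tpr, auc) by threshold sweep over unique scores, trapezoid area."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], positive[order]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last index of each run of equal scores
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def roc_auc(
    class_scores: np.ndarray, true_labels: list[str], classes: list[str]
) -> ROCResult:
    """Per-class one-vs-rest ROC; macro AUC over classes with both outcomes."""
    S = np.asarray(class_scores, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValidationError("scores must be finite")
    if S.shape != (len(true_labels), len(classes)):
        raise ValidationError("score matrix shape must be (n_samples, n_classes)")
    if len(set(true_labels)) < 2:
        raise ValidationError("AUC undefined for single-class truth")
    y = np.array(true_labels)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    aucs: dict[str, float] = {}
    for j, c in enumerate(classes):
        pos = y == c
        if pos.all() or not pos.any():
            continue  # no ROC without both outcomes
        fpr, tpr, auc = _binary_roc(S[:, j], pos)
        curves[c] = (fpr, tpr)
        aucs[c] = auc
    if not aucs:
        raise ValidationError("no class has both positive and negative samples")
    return ROCResult(curves=curves, auc_per_class=aucs, macro_auc=float(np.mean(list(aucs.values()))))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialisable to/from YAML or JSON."""

    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    feature_count: int = 15
    d_min: float = autolabel.D_MIN_DEFAULT
    use_q_labeler: bool = True
    qlearner: autolabel.QLearnerConfig = field(default_factory=autolabel.QLearnerConfig)
    hidden: int = 8
    federated_cfg: federated.FederatedConfig = field(default_factory=federated.FederatedConfig)
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    unlabeled_grid: tuple[float, ...] = (0.30, 0.50, 0.70, 0.90, 0.999)
    feature_grid: tuple[int, ...] = (4, 45)
    seed: int = 0

    def reseeded(self, seed: int) -> "RunConfig":
        """Derive a copy with every stage seed re-keyed from ``seed``."""
        return dataclasses.replace(
            self,
            seed=seed,
            synthetic=dataclasses.replace(self.synthetic, seed=seed),
            qlearner=dataclasses.replace(self.qlearner, seed=seed + 1),
            federated_cfg=dataclasses.replace(
                self.federated_cfg,
                seed=seed + 2,
                local=dataclasses.replace(self.federated_cfg.local, seed=seed + 3),
            ),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            for k in ("activities", "positions", "class_freq", "class_amp"):
                if k in syn and syn[k] is not None:
                    syn[k] = tuple(syn[k])
            d["synthetic"] = synthetic.SyntheticConfig(**syn)
        if "qlearner" in d:
            d["qlearner"] = autolabel.QLearnerConfig(**d["qlearner"])
        if "federated_cfg" in d:
            fd = dict(d["federated_cfg"])
            if "local" in fd:
                fd["local"] = neural.TrainingConfig(**fd["local"])
            d["federated_cfg"] = federated.FederatedConfig(**fd)
        for k in ("fractions", "unlabeled_grid", "feature_grid"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    metrics: MetricsReport
    roc: ROCResult | None
    comm: federated.CommunicationReport | None
    round_logs: list[federated.RoundLog]
    params: neural.BiLSTMParams
    threshold: float | None
    propagation_accuracy: float | None  # vs hidden ground truth
    propagation_coverage: float | None  # assigned / unlabeled
    n_windows: int
    n_test: int


def _prepare_dataset(cfg: RunConfig) -> tuple[Dataset, synthetic.GroundTruth]:
    """Generate, corrupt/clean if configured, window, featurize, standardize."""
    syn = cfg.synthetic
    records, truth = synthetic.generate_dataset(syn)
    if syn.duplicate_rate > 0 or syn.missing_rate > 0:
        records = synthetic.inject_defects(
            records, syn.duplicate_rate, syn.missing_rate, syn.seed + 17
        )
    records = ingest.clean_records(records)
    windows = ingest.segment_windows(records, syn.window_len, syn.window_len)
    ds = Dataset(
        windows=windows,
        person_contexts=synthetic.generate_subjects(syn.n_subjects, syn.seed),
        device_registry=synthetic.make_device_registry(syn.positions),
    )
    ingest.featurize_dataset(ds, cfg.feature_count)
    # one global standardisation so the classifier's context block is scaled;
    # z-scores are clipped so near-constant features cannot blow up distances
    F = np.stack([w.features for w in ds.windows])
    mean, scale = F.mean(axis=0), F.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    for w in ds.windows:
        w.features = np.clip((w.features - mean) / scale, -10.0, 10.0)
    return ds, truth


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Auto-label, federated-train and evaluate one synthetic scenario."""
    ds, truth = _prepare_dataset(cfg)
    ingest.split_dataset(ds, cfg.fractions, cfg.seed + 11)
    train = ds.subset("train")
    test = ds.subset("test")
    labeled_train = [w for w in train if w.label is not None]
    unlabeled_train = [w for w in train if w.label is None]
    classes = tuple(sorted(cfg.synthetic.activities))

    threshold = prop_acc = coverage = None
    # propagation needs at least two labeled classes to calibrate against
    can_propagate = (
        len(unlabeled_train) > 0
        and len({w.label for w in labeled_train}) >= 2
        and len(train) >= len(classes)
    )
    if can_propagate:
        feats = np.stack([w.features for w in train])
        partial = [w.label for w in train]
        model = autolabel.fit_clusters(feats, partial, m=len(classes), seed=cfg.seed + 23)
        cal = autolabel.calibrate_threshold(
            np.stack([w.features for w in labeled_train]),
            [w.label for w in labeled_train],
            model,
            cfg.d_min,
        )
        threshold = cal.threshold
        sub = Dataset(windows=unlabeled_train)
        if cfg.use_q_labeler:
            assignments, _, _ = autolabel.run_q_autolabel(
                sub, model, threshold, cfg.qlearner, cfg.d_min
            )
        else:
            assignments, _ = autolabel.propagate_labels(
                unlabeled_train, model, threshold, cfg.d_min
            )
        if assignments:
            correct = sum(1 for wid, lab, _ in assignments if truth.labels[wid] == lab)
            prop_acc = correct / len(assignments)
        coverage = len(assignments) / len(unlabeled_train)
        autolabel.apply_assignments(ds, assignments)
        labeled_train = [w for w in train if w.label is not None]

    params0 = neural.init_bilstm(
        n_inputs=cfg.synthetic.n_channels,
        hidden=cfg.hidden,
        n_classes=len(classes),
        extra_dim=cfg.feature_count,
        seed=cfg.seed + 31,
        classes=classes,
    )
    if labeled_train:
        n_clients = min(cfg.federated_cfg.n_clients, len(labeled_train))
        fed_cfg = (
            cfg.federated_cfg
            if n_clients == cfg.federated_cfg.n_clients
            else dataclasses.replace(cfg.federated_cfg, n_clients=n_clients)
        )
        clients = federated.partition_clients(
            labeled_train, fed_cfg.n_clients, fed_cfg.scheme, fed_cfg.seed
        )
        params, logs = federated.run_federated(params0, clients, fed_cfg)
    else:
        logger.warning("no labeled training windows; evaluating the untrained model")
        params, logs = params0, []

    y_true = [truth.labels[w.window_id] for w in test]
    scores = neural.predict_scores(params, test)
    y_pred = [classes[int(i)] for i in np.argmax(scores, axis=1)]
    metrics = compute_metrics(y_true, y_pred)
    roc = None
    if len(set(y_true)) >= 2:
        roc = roc_auc(neural.sparsemax(scores), y_true, list(classes))

    n_records = sum(w.samples.shape[0] for w in ds.windows)
    comm = federated.communication_report(
        logs,
        federated.raw_dataset_bytes(n_records, cfg.synthetic.n_channels),
    ) if logs else None
    return PipelineResult(
        metrics=metrics,
        roc=roc,
        comm=comm,
        round_logs=logs,
        params=params,
        threshold=threshold,
        propagation_accuracy=prop_acc,
        propagation_coverage=coverage,
        n_windows=len(ds.windows),
        n_test=len(test),
    )


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def _result_row(res: PipelineResult) -> dict:
    return {
        "accuracy": res.metrics.accuracy,
        "macro_precision": res.metrics.macro_precision,
        "macro_recall": res.metrics.macro_recall,
        "macro_f1": res.metrics.macro_f1,
        "macro_auc": res.roc.macro_auc if res.roc else np.nan,
        "propagation_accuracy": np.nan
        if res.propagation_accuracy is None
        else res.propagation_accuracy,
        "propagation_coverage": np.nan
        if res.propagation_coverage is None
        else res.propagation_coverage,
        "n_test": res.n_test,
        "seed": np.nan,
    }


def unlabeled_sweep(cfg: RunConfig, fractions=None) -> pd.DataFrame:
    """Re-run the pipeline per unlabeled fraction; one metrics row each."""
    fractions = tuple(cfg.unlabeled_grid if fractions is None else fractions)
    if any(not 0.0 <= f <= 0.999 for f in fractions):
        raise ValidationError("fractions must lie in [0, 0.999]")
    rows = []
    for f in fractions:
        sub = dataclasses.replace(
            cfg, synthetic=dataclasses.replace(cfg.synthetic, unlabeled_fraction=f)
        )
        res = run_pipeline(sub)
        row = {"unlabeled_fraction": f, **_result_row(res)}
        row["seed"] = cfg.seed
        rows.append(row)
        logger.info("unlabeled sweep %.3f: macro F1 %.3f", f, row["macro_f1"])
    return pd.DataFrame(rows)


def feature_sweep(cfg: RunConfig, feature_counts=None) -> pd.DataFrame:
    """Re-run the pipeline per feature-vector length; one metrics row each."""
    counts = tuple(cfg.feature_grid if feature_counts is None else feature_counts)
    if any(not ingest.MIN_FEATURES <= c <= ingest.MAX_FEATURES for c in counts):
        raise ValidationError("feature counts must lie in [4, 45]")
    rows = []
    for c in counts:
        sub = dataclasses.replace(cfg, feature_count=int(c))
        res = run_pipeline(sub)
        row = {"feature_count": int(c), **_result_row(res)}
        row["seed"] = cfg.seed
        rows.append(row)
        logger.info("feature sweep %d: macro F1 %.3f", c, row["macro_f1"])
    return pd.DataFrame(rows)
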
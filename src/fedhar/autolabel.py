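"""Cluster-based auto-labeling of unlabeled sensor windows.

The scheme clusters the standardized feature space with k-means, maps each
cluster to the majority label of its labeled members, and scores every
unlabeled window by the propagation entropy

    omega = -ln(max(d, d_min))

where d is the Euclidean distance ("interspace") to the nearest mapped
centroid.  A window receives that cluster's label iff omega strictly
exceeds a threshold calibrated on the labeled training data by maximising
F1 over the precision-recall curve (positives = correctly propagated
points).  A deep-Q-learning loop wraps the same decision: the propagation
rule acts as the reward oracle (+omega for agreeing with it, -omega
otherwise), experiences are replayed into a linear action-value model whose
target copy is resynchronised every fixed number of steps, and the trained
greedy policy produces the final labels.  On separable data the policy
converges to the propagation rule itself.

Distances are always computed in standardized feature space; d is clamped
below at d_min so omega stays finite (negative omega for d > 1 is allowed
and simply fails any non-negative threshold).
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2

from .ingest import Dataset, ValidationError, Window

logger = logging.getLogger("fedhar")

D_MIN_DEFAULT = 1e-12


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """k-means centroids in standardized feature space plus a label map."""

    centroids: np.ndarray  # (m, d), standardized space
    label_map: dict[int, str]  # mapped clusters only (majority vote)
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def m(self) -> int:
        return self.centroids.shape[0]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_scale

    def mapped_ids(self) -> list[int]:
        return sorted(self.label_map)


def fit_clusters(
    features: np.ndarray,
    labels_partial: list[str | None],
    m: int,
    seed: int = 0,
) -> ClusterModel:
    """k-means with m centroids on standardized features.

    Each cluster takes the majority label of its labeled members (ties
    broken lexicographically); clusters with no labeled member stay
    unmapped.  Degenerate inputs (all points identical) yield duplicate
    centroids with assignment to the lowest cluster index.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D array")
    n = X.shape[0]
    if m < 2:
        raise ValidationError(f"m must be >= 2, got {m}")
    if m > n:
        raise ValidationError(f"m={m} exceeds the {n} available points")
    if all(lab is None for lab in labels_partial):
        raise ValidationError("need at least one labeled point")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    Z = (X - mean) / scale

    if np.allclose(Z, Z[0]):  # all points identical: kmeans2 cannot spread
        centroids = np.tile(Z[0], (m, 1))
        assign = np.zeros(n, dtype=int)
    else:
        # ten seeded restarts, keep the lowest within-cluster sum of squares
        best = None
        for restart in range(10):
            with np.errstate(all="ignore"):
                cents, asg = kmeans2(
                    Z, m, minit="++", seed=(abs(seed) + 7919 * restart) % (2**31)
                )
            inertia = float(np.sum((Z - cents[asg]) ** 2))
            if best is None or inertia < best[0]:
                best = (inertia, cents, asg)
        _, centroids, assign = best
    label_map: dict[int, str] = {}
    for c in range(m):
        members = [
            labels_partial[i]
            for i in np.flatnonzero(assign == c)
            if labels_partial[i] is not None
        ]
        if members:
            counts = Counter(members)
            top = max(counts.values())
            label_map[c] = min(lab for lab, k in counts.items() if k == top)
    if not np.all(np.isfinite(centroids)):
        raise ValidationError("non-finite centroid produced")
    return ClusterModel(
        centroids=centroids, label_map=label_map, feature_mean=mean, feature_scale=scale
    )


# ---------------------------------------------------------------------------
# Propagation weight (interspace entropy)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropagationWeight:
    """Entropy weight omega = -ln(max(d, d_min)) to a source cluster."""

    omega: float
    cluster_id: int
    distance: float


def interspace_weight(
    x: np.ndarray, centroid: np.ndarray, d_min: float = D_MIN_DEFAULT, cluster_id: int = -1
) -> PropagationWeight:
    """Propagation weight of a standardized point to one centroid."""
    x = np.asarray(x, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if x.shape != centroid.shape:
        raise ValidationError(
            f"dimension mismatch: point {x.shape} vs centroid {centroid.shape}"
        )
    if d_min <= 0:
        raise ValidationError("d_min must be > 0")
    d = float(np.linalg.norm(x - centroid))
    return PropagationWeight(
        omega=float(-np.log(max(d, d_min))), cluster_id=cluster_id, distance=d
    )


def nearest_mapped(
    x_raw: np.ndarray, model: ClusterModel, d_min: float = D_MIN_DEFAULT
) -> tuple[str, PropagationWeight]:
    """(label, weight) for the nearest *mapped* centroid of a raw point.

    Model-level distances are per-coordinate RMS (Euclidean / sqrt(p)), a
    monotone rescaling that keeps omega's sign meaningful regardless of the
    feature count: tight clusters give d << 1 hence omega > 0.
    """
    mapped = model.mapped_ids()
    if not mapped:
        raise ValidationError("cluster model has no mapped cluster")
    z = model.standardize(x_raw)
    dists = np.linalg.norm(model.centroids[mapped] - z, axis=1) / np.sqrt(z.size)
    best = int(np.argmin(dists))
    cid = mapped[best]
    d = float(dists[best])
    w = PropagationWeight(
        omega=float(-np.log(max(d, d_min))), cluster_id=cid, distance=d
    )
    return model.label_map[cid], w


def omega_vector(
    x_raw: np.ndarray, model: ClusterModel, d_min: float = D_MIN_DEFAULT
) -> np.ndarray:
    """Per-cluster omega values (all m clusters) — part of the Q state."""
    z = model.standardize(x_raw)
    d = np.linalg.norm(model.centroids - z, axis=1) / np.sqrt(z.size)
    return -np.log(np.maximum(d, d_min))


# ---------------------------------------------------------------------------
# Threshold calibration (precision-recall curve)
# ---------------------------------------------------------------------------


@dataclass
class ThresholdCalibration:
    """Max-F1 operating point of the propagation precision-recall sweep."""

    threshold: float
    curve: list[tuple[float, float, float, float]]  # (threshold, P, R, F1)
    f1: float


def calibrate_threshold(
    labeled_features: np.ndarray,
    labeled_labels: list[str],
    model: ClusterModel,
    d_min: float = D_MIN_DEFAULT,
) -> ThresholdCalibration:
    """Sweep thresholds over the observed omega values of labeled points.

    A point is "retrieved" at threshold t iff its omega to the nearest
    mapped centroid strictly exceeds t; a retrieval is a true positive iff
    the propagated label matches the point's true label.  Precision and
    recall are computed over retrievals with correctly-propagated points as
    the positive class; the returned threshold maximises F1 (ties go to the
    larger threshold).  If no candidate label is ever correct the sentinel
    +inf is returned (propagate nothing).
    """
    X = np.asarray(labeled_features, dtype=float)
    if X.shape[0] == 0:
        raise ValidationError("labeled training set is empty")
    if len(set(labeled_labels)) < 2:
        raise ValidationError("threshold calibration needs >= 2 classes")
    omegas = np.empty(X.shape[0])
    correct = np.empty(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        lab, w = nearest_mapped(X[i], model, d_min)
        omegas[i] = w.omega
        correct[i] = lab == labeled_labels[i]
    total_correct = int(correct.sum())
    if total_correct == 0:
        return ThresholdCalibration(threshold=np.inf, curve=[], f1=0.0)

    # candidates: just below the minimum (retrieve all) and each observed omega
    candidates = np.concatenate([[omegas.min() - 1.0], np.unique(omegas)])
    curve: list[tuple[float, float, float, float]] = []
    best_t, best_f1 = np.inf, -1.0
    for t in candidates:
        retrieved = omegas > t
        n_ret = int(retrieved.sum())
        tp = int((retrieved & correct).sum())
        precision = tp / n_ret if n_ret else 0.0
        recall = tp / total_correct
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        curve.append((float(t), precision, recall, f1))
        if f1 > best_f1 or (f1 == best_f1 and t > best_t):
            best_f1, best_t = f1, float(t)
    return ThresholdCalibration(threshold=best_t, curve=curve, f1=best_f1)


# ---------------------------------------------------------------------------
# Label propagation
# ---------------------------------------------------------------------------


def propagate_labels(
    unlabeled_windows: list[Window],
    model: ClusterModel,
    threshold: float,
    d_min: float = D_MIN_DEFAULT,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Assign each window its nearest mapped cluster's label iff omega > threshold.

    Returns (assignments, abstentions): assignments as (window_id, label,
    omega) triples; ties with the threshold abstain (strict inequality).
    """
    assignments: list[tuple[str, str, float]] = []
    abstentions: list[str] = []
    for w in unlabeled_windows:
        lab, pw = nearest_mapped(w.features, model, d_min)
        if pw.omega > threshold:
            assignments.append((w.window_id, lab, pw.omega))
        else:
            abstentions.append(w.window_id)
    return assignments, abstentions


def reward(action_label: str, oracle_label: str, omega: float) -> float:
    """+omega when the action matches the oracle, -omega otherwise."""
    if not np.isfinite(omega):
        raise ValidationError("omega must be finite")
    return omega if action_label == oracle_label else -omega


# ---------------------------------------------------------------------------
# Deep-Q auto-labeling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QLearnerConfig:
    """Episode/step counts and optimisation knobs for the Q auto-labeler.

    The target action-value copy is resynchronised every
    ``target_sync_steps`` gradient steps (150 by default); exploration
    decays exponentially from ``eps_start`` to ``eps_end``.
    """

    episodes: int = 30
    steps_per_episode: int = 200
    discount_factor: float = 0.9
    learning_rate: float = 0.05
    batch_size: int = 32
    target_sync_steps: int = 150
    eps_start: float = 1.0
    eps_end: float = 0.05
    eps_decay: float = 0.995
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_factor <= 1.0:
            raise ValidationError("discount_factor must be in [0, 1]")
        if self.target_sync_steps < 1:
            raise ValidationError("target_sync_steps must be >= 1")


@dataclass
class QModel:
    """Linear per-action value map with an online and a lagged target copy."""

    theta: np.ndarray  # (n_actions, state_dim + 1), last column is bias
    theta_target: np.ndarray

    def values(self, state: np.ndarray, target: bool = False) -> np.ndarray:
        W = self.theta_target if target else self.theta
        return W[:, :-1] @ state + W[:, -1]

    def sync(self) -> None:
        self.theta_target = self.theta.copy()


@dataclass(frozen=True)
class Experience:
    """One replayed transition (state, action index, reward, next state)."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool


def q_target(exp: Experience, model: QModel, discount_factor: float) -> float:
    """Bootstrapped target: r, plus discounted max target-value if non-terminal."""
    if exp.terminal:
        return exp.reward
    return exp.reward + discount_factor * float(
        np.max(model.values(exp.next_state, target=True))
    )


@dataclass
class QTrainingLog:
    episode_mean_reward: list[float] = field(default_factory=list)
    n_experiences: int = 0


def run_q_autolabel(
    dataset: Dataset,
    model: ClusterModel,
    threshold: float,
    config: QLearnerConfig,
    d_min: float = D_MIN_DEFAULT,
) -> tuple[list[tuple[str, str, float]], list[str], QTrainingLog]:
    """Train a Q-policy against the propagation oracle and label greedily.

    Each step visits a random unlabeled window: the oracle is the
    propagation rule (nearest mapped cluster's label when omega exceeds the
    threshold; abstaining steps contribute no experience), the epsilon-
    greedy action is rewarded +/-omega, and replayed mini-batches descend
    the squared error to the bootstrapped target.  The final labeling
    applies the greedy policy wherever the oracle propagates, abstaining
    elsewhere.  Returns (assignments, abstentions, log).
    """
    unlabeled = [w for w in dataset.windows if w.label is None]
    log = QTrainingLog()
    if not unlabeled:
        logger.warning("no unlabeled windows; Q auto-labeling is a no-op")
        return [], [], log

    actions = sorted(set(model.label_map.values()))
    action_index = {lab: i for i, lab in enumerate(actions)}
    rng = np.random.default_rng(config.seed)

    # precompute per-window state, oracle label and omega
    states, oracle, omegas = [], [], []
    for w in unlabeled:
        lab, pw = nearest_mapped(w.features, model, d_min)
        states.append(np.concatenate([model.standardize(w.features),
                                      omega_vector(w.features, model, d_min)]))
        oracle.append(lab if pw.omega > threshold else None)
        omegas.append(pw.omega)

    state_dim = states[0].size
    theta0 = rng.normal(0.0, 0.01, size=(len(actions), state_dim + 1))
    qmodel = QModel(theta=theta0, theta_target=theta0.copy())
    replay: deque[Experience] = deque(maxlen=10 * config.steps_per_episode)

    eps = config.eps_start
    grad_steps = 0
    for _ in range(config.episodes):
        visit = rng.integers(0, len(unlabeled), size=config.steps_per_episode + 1)
        ep_rewards: list[float] = []
        for t in range(config.steps_per_episode):
            i = int(visit[t])
            if oracle[i] is None:
                continue  # oracle abstains: no experience
            s = states[i]
            if rng.random() < eps:
                a = int(rng.integers(0, len(actions)))
            else:
                a = int(np.argmax(qmodel.values(s)))
            r = reward(actions[a], oracle[i], omegas[i])
            ep_rewards.append(r)
            replay.append(
                Experience(
                    state=s,
                    action=a,
                    reward=r,
                    next_state=states[int(visit[t + 1])],
                    terminal=(t == config.steps_per_episode - 1),
                )
            )
            eps = max(config.eps_end, eps * config.eps_decay)
            if len(replay) >= config.batch_size:
                batch_idx = rng.integers(0, len(replay), size=config.batch_size)
                for j in batch_idx:
                    exp = replay[int(j)]
                    o_j = q_target(exp, qmodel, config.discount_factor)
                    q_sa = float(qmodel.values(exp.state)[exp.action])
                    err = q_sa - o_j
                    qmodel.theta[exp.action, :-1] -= (
                        config.learning_rate / config.batch_size * err * exp.state
                    )
                    qmodel.theta[exp.action, -1] -= (
                        config.learning_rate / config.batch_size * err
                    )
                grad_steps += 1
                if grad_steps % config.target_sync_steps == 0:
                    qmodel.sync()
        log.episode_mean_reward.append(
            float(np.mean(ep_rewards)) if ep_rewards else 0.0
        )
    log.n_experiences = len(replay)

    assignments: list[tuple[str, str, float]] = []
    abstentions: list[str] = []
    for i, w in enumerate(unlabeled):
        if oracle[i] is None:
            abstentions.append(w.window_id)
        else:
            a = int(np.argmax(qmodel.values(states[i])))
            assignments.append((w.window_id, actions[a], omegas[i]))
    return assignments, abstentions, log


def apply_assignments(
    dataset: Dataset, assignments: list[tuple[str, str, float]]
) -> Dataset:
    """Write propagated labels back into the windows (provenance 'propagated')."""
    by_id = {w.window_id: w for w in dataset.windows}
    for wid, lab, _ in assignments:
        w = by_id[wid]
        w.label = lab
        w.label_provenance = "propagated"
    return dataset


def write_provenance(assignments, abstentions, path) -> None:
    """Sidecar CSV: window_id, label, omega, provenance."""
    import pandas as pd

    rows = [[wid, lab, om, "propagated"] for wid, lab, om in assignments]
    rows += [[wid, "", np.nan, "none"] for wid in abstentions]
    pd.DataFrame(rows, columns=["window_id", "label", "omega", "provenance"]).to_csv(
        path, index=False
    )
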
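"""From-scratch BiLSTM activity classifier with sparsemax output.

The classifier consumes a window's raw sample matrix (time x channels) with
two independent LSTM passes (forward and backward in time), concatenates
the two final hidden states, optionally appends the window's feature/context
vector, and projects linearly to per-class scores.  Scores go through
sparsemax — the Euclidean projection onto the probability simplex — paired
with its canonical loss, whose gradient is simply sparsemax(z) - onehot(y).

Each LSTM direction follows the standard gate equations

    f = sigmoid(Wf [h, x] + bf)      i = sigmoid(Wi [h, x] + bi)
    g = tanh(Wc [h, x] + bc)         o = sigmoid(Wo [h, x] + bo)
    c' = f * c + i * g               h' = o * tanh(c')

Training is plain SGD over mini-batches with an additive Gaussian-noise
layer on the inputs and inverted dropout on the concatenated hidden states;
both are identity at inference.  All gradients are computed analytically
(backpropagation through time) and are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .ingest import ValidationError, Window

GATES = ("Wf", "Wi", "Wc", "Wo", "bf", "bi", "bc", "bo")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class BiLSTMParams:
    """All weights of the two directions plus the output projection.

    ``arrays`` maps flat names (``f/Wf`` ... ``b/bo``, ``out/W``,
    ``out/b``) to ndarrays; federated averaging and SGD act on this dict.
    """

    arrays: dict[str, np.ndarray]
    hidden: int
    n_inputs: int
    n_classes: int
    extra_dim: int
    classes: tuple[str, ...] = ()

    def copy(self) -> "BiLSTMParams":
        return BiLSTMParams(
            arrays={k: v.copy() for k, v in self.arrays.items()},
            hidden=self.hidden,
            n_inputs=self.n_inputs,
            n_classes=self.n_classes,
            extra_dim=self.extra_dim,
            classes=self.classes,
        )

    def direction(self, tag: str) -> dict[str, np.ndarray]:
        return {g: self.arrays[f"{tag}/{g}"] for g in GATES}

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.arrays.values())


def init_bilstm(
    n_inputs: int,
    hidden: int,
    n_classes: int,
    extra_dim: int = 0,
    seed: int = 0,
    scale: float = 0.1,
    classes: tuple[str, ...] = (),
) -> BiLSTMParams:
    """Random initialisation; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    u = hidden + n_inputs
    for tag in ("f", "b"):
        for g in ("Wf", "Wi", "Wc", "Wo"):
            arrays[f"{tag}/{g}"] = rng.normal(0.0, scale, size=(hidden, u))
        for g in ("bf", "bi", "bc", "bo"):
            arrays[f"{tag}/{g}"] = np.zeros(hidden)
    proj_in = 2 * hidden + extra_dim
    arrays["out/W"] = rng.normal(0.0, scale, size=(n_classes, proj_in))
    arrays["out/b"] = np.zeros(n_classes)
    return BiLSTMParams(
        arrays=arrays,
        hidden=hidden,
        n_inputs=n_inputs,
        n_classes=n_classes,
        extra_dim=extra_dim,
        classes=classes,
    )


@dataclass
class BiLSTMState:
    """Gate activations and states after one cell step."""

    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    candidate: np.ndarray
    cell: np.ndarray
    hidden: np.ndarray


def lstm_cell_step(
    params_dir: dict[str, np.ndarray],
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> BiLSTMState:
    """One LSTM cell update on vectors (reference, unbatched)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H = params_dir["Wf"].shape[0]
    if params_dir["Wf"].shape[1] != h_prev.size + x_t.size or c_prev.size != H:
        raise ValidationError("lstm_cell_step: inconsistent shapes")
    u = np.concatenate([h_prev, x_t])
    f = _sigmoid(params_dir["Wf"] @ u + params_dir["bf"])
    i = _sigmoid(params_dir["Wi"] @ u + params_dir["bi"])
    g = np.tanh(params_dir["Wc"] @ u + params_dir["bc"])
    o = _sigmoid(params_dir["Wo"] @ u + params_dir["bo"])
    c_new = f * c_prev + i * g
    h_new = o * np.tanh(c_new)
    return BiLSTMState(f=f, i=i, o=o, candidate=g, cell=c_new, hidden=h_new)


# ---------------------------------------------------------------------------
# Batched forward / backward
# ---------------------------------------------------------------------------


def _direction_forward(p: dict[str, np.ndarray], X: np.ndarray):
    """Run one direction over X (batch, T, channels); returns final h + cache."""
    B, T, _ = X.shape
    H = p["Wf"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        u = np.concatenate([h, X[:, t, :]], axis=1)
        f = _sigmoid(u @ p["Wf"].T + p["bf"])
        i = _sigmoid(u @ p["Wi"].T + p["bi"])
        g = np.tanh(u @ p["Wc"].T + p["bc"])
        o = _sigmoid(u @ p["Wo"].T + p["bo"])
        c_new = f * c + i * g
        h = o * np.tanh(c_new)
        cache.append((u, f, i, g, o, c))
        c = c_new
    return h, cache, c


def _direction_backward(
    p: dict[str, np.ndarray], cache, dh_final: np.ndarray
) -> dict[str, np.ndarray]:
    """BPTT for one direction; gradient enters only at the final hidden state."""
    H = p["Wf"].shape[0]
    grads = {g: np.zeros_like(p[g]) for g in GATES}
    dh = dh_final
    dc = np.zeros_like(dh_final)
    c_after = None
    for t in range(len(cache) - 1, -1, -1):
        u, f, i, g, o, c_prev = cache[t]
        c_new = f * c_prev + i * g
        tc = np.tanh(c_new)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dzf = df * f * (1.0 - f)
        dzi = di * i * (1.0 - i)
        dzo = do * o * (1.0 - o)
        dzg = dg * (1.0 - g * g)
        grads["Wf"] += dzf.T @ u
        grads["Wi"] += dzi.T @ u
        grads["Wc"] += dzg.T @ u
        grads["Wo"] += dzo.T @ u
        grads["bf"] += dzf.sum(axis=0)
        grads["bi"] += dzi.sum(axis=0)
        grads["bc"] += dzg.sum(axis=0)
        grads["bo"] += dzo.sum(axis=0)
        du = dzf @ p["Wf"] + dzi @ p["Wi"] + dzg @ p["Wc"] + dzo @ p["Wo"]
        dh = du[:, :H]
        dc = dc * f
        c_after = c_new  # noqa: F841  (kept for clarity of the recurrence)
    return grads


def forward_scores(
    params: BiLSTMParams,
    X: np.ndarray,
    extra: np.ndarray | None = None,
    dropout_mask: np.ndarray | None = None,
):
    """Class scores for a batch; returns (scores, cache for backprop)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] < 1:
        raise ValidationError("X must be (batch, time>=1, channels)")
    hf, cache_f, _ = _direction_forward(params.direction("f"), X)
    hb, cache_b, _ = _direction_forward(params.direction("b"), X[:, ::-1, :])
    hcat = np.concatenate([hf, hb], axis=1)
    if dropout_mask is not None:
        hcat = hcat * dropout_mask
    if params.extra_dim:
        if extra is None or extra.shape[1] != params.extra_dim:
            raise ValidationError("extra feature block missing or wrong width")
        proj_in = np.concatenate([hcat, extra], axis=1)
    else:
        proj_in = hcat
    Z = proj_in @ params.arrays["out/W"].T + params.arrays["out/b"]
    return Z, (cache_f, cache_b, proj_in, dropout_mask)


def backward_scores(
    params: BiLSTMParams, cache, dZ: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of a scalar objective wrt all parameters, given dL/dZ."""
    cache_f, cache_b, proj_in, dropout_mask = cache
    H = params.hidden
    grads: dict[str, np.ndarray] = {
        "out/W": dZ.T @ proj_in,
        "out/b": dZ.sum(axis=0),
    }
    dproj = dZ @ params.arrays["out/W"]
    dhcat = dproj[:, : 2 * H]
    if dropout_mask is not None:
        dhcat = dhcat * dropout_mask
    gf = _direction_backward(params.direction("f"), cache_f, dhcat[:, :H])
    gb = _direction_backward(params.direction("b"), cache_b, dhcat[:, H:])
    for g in GATES:
        grads[f"f/{g}"] = gf[g]
        grads[f"b/{g}"] = gb[g]
    return grads


def bilstm_forward(
    params: BiLSTMParams, sequence: np.ndarray, extra: np.ndarray | None = None
) -> np.ndarray:
    """Class scores for a single (time, channels) sequence."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValidationError("sequence must be non-empty (time, channels)")
    X = seq[None, :, :]
    ex = None
    if params.extra_dim:
        ex = np.asarray(extra, dtype=float).reshape(1, -1)
    Z, _ = forward_scores(params, X, ex)
    return Z[0]


# ---------------------------------------------------------------------------
# Sparsemax and its loss
# ---------------------------------------------------------------------------


def sparsemax(z: np.ndarray) -> np.ndarray:
    """Euclidean projection of score vector(s) onto the probability simplex.

    Sort scores descending, find the support size
    k = max{k : 1 + k z_(k) > sum_{j<=k} z_(j)}, set
    tau = (sum of supported scores - 1)/k and p_i = max(z_i - tau, 0).
    Accepts a vector or a (batch, K) matrix.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("sparsemax requires finite scores")
    single = z.ndim == 1
    Z = z[None, :] if single else z
    srt = np.sort(Z, axis=1)[:, ::-1]
    cum = np.cumsum(srt, axis=1)
    ks = np.arange(1, Z.shape[1] + 1)
    support = 1.0 + ks * srt > cum
    k_z = support.sum(axis=1)
    tau = (cum[np.arange(Z.shape[0]), k_z - 1] - 1.0) / k_z
    P = np.maximum(Z - tau[:, None], 0.0)
    return P[0] if single else P


def _sparsemax_tau(z_row: np.ndarray) -> float:
    srt = np.sort(z_row)[::-1]
    cum = np.cumsum(srt)
    ks = np.arange(1, z_row.size + 1)
    k_z = int((1.0 + ks * srt > cum).sum())
    return float((cum[k_z - 1] - 1.0) / k_z)


def sparsemax_loss(z: np.ndarray, y: int) -> tuple[float, np.ndarray]:
    """Canonical sparsemax loss and its gradient for one score vector.

    loss = -z_y + 1/2 sum_{j in support} (z_j^2 - tau^2) + 1/2;
    grad = sparsemax(z) - onehot(y).  Non-negative, zero exactly when the
    projection already puts all mass on the true class.
    """
    z = np.asarray(z, dtype=float)
    if not (np.issubdtype(type(y), np.integer) or isinstance(y, int)) or not (
        0 <= y < z.size
    ):
        raise ValidationError(f"invalid class index {y!r} for {z.size} classes")
    p = sparsemax(z)
    tau = _sparsemax_tau(z)
    support = p > 0
    loss = float(-z[y] + 0.5 * np.sum(z[support] ** 2 - tau**2) + 0.5)
    grad = p.copy()
    grad[y] -= 1.0
    return loss, grad


def sparsemax_loss_batch(Z: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean sparsemax loss over a batch and dL/dZ (already /batch)."""
    B = Z.shape[0]
    P = sparsemax(Z)
    losses = np.empty(B)
    for b in range(B):
        tau = _sparsemax_tau(Z[b])
        support = P[b] > 0
        losses[b] = -Z[b, y_idx[b]] + 0.5 * np.sum(Z[b, support] ** 2 - tau**2) + 0.5
    dZ = P.copy()
    dZ[np.arange(B), y_idx] -= 1.0
    return float(losses.mean()), dZ / B


# ---------------------------------------------------------------------------
# Stochastic layers
# ---------------------------------------------------------------------------


def gaussian_noise(
    x: np.ndarray, std: float, training: bool, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Additive N(0, std) corruption in training mode; identity otherwise."""
    if std < 0:
        raise ValidationError("std must be >= 0")
    if not training or std == 0:
        return np.asarray(x, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.asarray(x, dtype=float) + rng.normal(0.0, std, size=np.shape(x))


def dropout(
    x: np.ndarray, rate: float, training: bool, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inverted dropout: zero with probability ``rate``, survivors / (1-rate)."""
    if not 0.0 <= rate < 1.0:
        raise ValidationError("rate must be in [0, 1)")
    if not training or rate == 0:
        return np.asarray(x, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = (rng.random(np.shape(x)) >= rate) / (1.0 - rate)
    return np.asarray(x, dtype=float) * mask


# ---------------------------------------------------------------------------
# Local training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyperparameters for local training.

    Defaults follow the reference experimental setting: learning rate 0.06
    and dropout 0.32 (an alternative 0.5 is selectable); the quoted batch
    size of 28.6 is not an integer, so 32 is used.
    """

    learning_rate: float = 0.06
    dropout_rate: float = 0.32
    noise_std: float = 0.01
    batch_size: int = 32
    iterations: int = 5
    loss_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1 or self.iterations < 1:
            raise ValidationError("batch_size and iterations must be >= 1")


def _stack_windows(
    windows: list[Window], classes: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    X = np.stack([np.asarray(w.samples, dtype=float) for w in windows])
    extra = None
    if windows[0].features is not None:
        extra = np.stack([np.asarray(w.features, dtype=float) for w in windows])
    idx = {c: i for i, c in enumerate(classes)}
    y = np.array([idx[w.label] for w in windows], dtype=int)
    return X, extra, y


def batch_loss_and_grads(
    params: BiLSTMParams,
    X: np.ndarray,
    extra: np.ndarray | None,
    y_idx: np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean loss over one batch and analytic gradients for every parameter."""
    Z, cache = forward_scores(params, X, extra, dropout_mask)
    loss, dZ = sparsemax_loss_batch(Z, y_idx)
    return loss, backward_scores(params, cache, dZ)


def train_local(
    params: BiLSTMParams, windows: list[Window], config: TrainingConfig
) -> tuple[BiLSTMParams, float]:
    """Mini-batch SGD on labeled windows; returns (new params, final mean loss).

    Each iteration (epoch): shuffle under the seed, then per mini-batch
    apply Gaussian input noise, the BiLSTM, dropout on the concatenated
    hidden states, and the sparsemax loss; update every parameter by
    learning_rate x gradient.  The input ``params`` object is not mutated.
    """
    labeled = [w for w in windows if w.label is not None]
    if not labeled:
        raise ValidationError("train_local requires labeled windows")
    classes = params.classes or tuple(sorted({w.label for w in labeled}))
    X_all, extra_all, y_all = _stack_windows(labeled, classes)
    rng = np.random.default_rng(config.seed)
    p = params.copy()
    p.classes = classes
    n = len(labeled)
    mean_loss = np.nan
    for _ in range(config.iterations):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            Xb = gaussian_noise(X_all[idx], config.noise_std, True, rng)
            mask = None
            if config.dropout_rate > 0:
                mask = (
                    rng.random((len(idx), 2 * p.hidden)) >= config.dropout_rate
                ) / (1.0 - config.dropout_rate)
            eb = extra_all[idx] if extra_all is not None else None
            loss, grads = batch_loss_and_grads(p, Xb, eb, y_all[idx], mask)
            losses.append(loss)
            if config.learning_rate:
                for k, g in grads.items():
                    p.arrays[k] -= config.learning_rate * g
        mean_loss = float(np.mean(losses))
    return p, mean_loss


def predict_scores(params: BiLSTMParams, windows: list[Window]) -> np.ndarray:
    """Inference-mode class scores (noise and dropout off) for windows."""
    X = np.stack([np.asarray(w.samples, dtype=float) for w in windows])
    extra = None
    if params.extra_dim:
        extra = np.stack([np.asarray(w.features, dtype=float) for w in windows])
    Z, _ = forward_scores(params, X, extra)
    return Z


def predict_labels(params: BiLSTMParams, windows: list[Window]) -> list[str]:
    Z = predict_scores(params, windows)
    return [params.classes[int(i)] for i in np.argmax(Z, axis=1)]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(params: BiLSTMParams, path, meta: dict | None = None) -> None:
    """HDF5 container with one named array per weight plus metadata attrs."""
    with h5py.File(path, "w") as f:
        for k, v in params.arrays.items():
            f.create_dataset(k, data=v)
        f.attrs["hidden"] = params.hidden
        f.attrs["n_inputs"] = params.n_inputs
        f.attrs["n_classes"] = params.n_classes
        f.attrs["extra_dim"] = params.extra_dim
        f.attrs["classes"] = ",".join(params.classes)
        for mk, mv in (meta or {}).items():
            f.attrs[f"meta/{mk}"] = mv


def load_checkpoint(path) -> BiLSTMParams:
    with h5py.File(path, "r") as f:
        arrays: dict[str, np.ndarray] = {}

        def _visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                arrays[name] = obj[()]

        f.visititems(_visit)
        classes = tuple(c for c in str(f.attrs["classes"]).split(",") if c)
        return BiLSTMParams(
            arrays=arrays,
            hidden=int(f.attrs["hidden"]),
            n_inputs=int(f.attrs["n_inputs"]),
            n_classes=int(f.attrs["n_classes"]),
            extra_dim=int(f.attrs["extra_dim"]),
            classes=classes,
        )
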
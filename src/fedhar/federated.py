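"""In-process federated-averaging simulation with byte accounting.

Clients are process-local holders of a labeled-window shard and a local
copy of the BiLSTM parameters.  Each round, a sampled subset of clients
downloads the global parameters, runs local SGD, and uploads its updated
parameters; the server forms the new global model as the sample-count-
weighted mean (FedAvg).  Training stops early once the participants'
weighted mean loss drops below a threshold.  Communication is accounted at
byte level — each transfer moves n_parameters x bytes_per_param (4-byte
floats by default); round-trip time is not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import Dataset, ValidationError, Window
from .neural import BiLSTMParams, TrainingConfig, train_local

logger = logging.getLogger("fedhar")


@dataclass
class ClientState:
    """One simulated edge client: its shard, local params and byte counters."""

    client_id: str
    shard: list[Window]
    params: BiLSTMParams | None = None
    bytes_sent: int = 0
    bytes_received: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.shard)


@dataclass
class RoundLog:
    """Bookkeeping for one federated round."""

    round_index: int
    participants: list[str]
    mean_loss: float
    bytes_up: int
    bytes_down: int


@dataclass(frozen=True)
class FederatedConfig:
    """Round count, participation, stopping rule and byte model."""

    n_clients: int = 5
    rounds: int = 10
    participation: float = 1.0
    loss_threshold: float = 0.0
    bytes_per_param: int = 4
    local: TrainingConfig = field(default_factory=TrainingConfig)
    scheme: str = "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.participation <= 1.0:
            raise ValidationError("participation must be in (0, 1]")
        if self.rounds < 1 or self.n_clients < 1:
            raise ValidationError("rounds and n_clients must be >= 1")
        if self.scheme not in ("iid", "by_subject"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def partition_clients(
    windows: list[Window], n_clients: int, scheme: str = "iid", seed: int = 0
) -> list[ClientState]:
    """Shard labeled windows across clients.

    ``iid``: a seeded uniform shuffle cut into near-equal shards.
    ``by_subject``: whole subjects per client (non-IID), subjects dealt
    round-robin in shuffled order.
    """
    if n_clients < 1:
        raise ValidationError("n_clients must be >= 1")
    rng = np.random.default_rng(seed)
    if scheme == "iid":
        if n_clients > len(windows):
            raise ValidationError(
                f"{n_clients} clients but only {len(windows)} windows"
            )
        order = rng.permutation(len(windows))
        shards = np.array_split(order, n_clients)
        return [
            ClientState(client_id=f"c{i}", shard=[windows[j] for j in shard])
            for i, shard in enumerate(shards)
        ]
    subjects = sorted({w.subject_id for w in windows})
    if n_clients > len(subjects):
        raise ValidationError(
            f"{n_clients} clients but only {len(subjects)} subjects to shard"
        )
    order = rng.permutation(len(subjects))
    owner = {subjects[j]: i % n_clients for i, j in enumerate(order)}
    clients = [ClientState(client_id=f"c{i}", shard=[]) for i in range(n_clients)]
    for w in windows:
        clients[owner[w.subject_id]].shard.append(w)
    return clients


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def federated_average(
    params_list: list[BiLSTMParams], sample_counts: list[int]
) -> BiLSTMParams:
    """Sample-count-weighted mean of every parameter array."""
    if not params_list or len(params_list) != len(sample_counts):
        raise ValidationError("need one sample count per params object")
    if any(c <= 0 for c in sample_counts):
        raise ValidationError("sample counts must be positive")
    ref = params_list[0]
    total = float(sum(sample_counts))
    out = ref.copy()
    for k in ref.arrays:
        acc = np.zeros_like(ref.arrays[k])
        for p, c in zip(params_list, sample_counts):
            if p.arrays[k].shape != ref.arrays[k].shape:
                raise ValidationError(f"shape mismatch for parameter {k!r}")
            acc += (c / total) * p.arrays[k]
        out.arrays[k] = acc
    return out


# ---------------------------------------------------------------------------
# Rounds
# ---------------------------------------------------------------------------


def run_round(
    global_params: BiLSTMParams,
    clients: list[ClientState],
    config: FederatedConfig,
    round_index: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[BiLSTMParams, RoundLog]:
    """One federated round: sample, download, train locally, upload, average."""
    if not clients:
        raise ValidationError("no clients")
    rng = rng or np.random.default_rng(config.seed + round_index)
    n_part = int(np.ceil(config.participation * len(clients)))
    chosen = sorted(rng.choice(len(clients), size=n_part, replace=False))
    per_transfer = global_params.n_parameters * config.bytes_per_param

    locals_, counts, losses = [], [], []
    for ci in chosen:
        client = clients[int(ci)]
        client.bytes_received += per_transfer  # downlink: global -> client
        local_cfg = TrainingConfig(
            learning_rate=config.local.learning_rate,
            dropout_rate=config.local.dropout_rate,
            noise_std=config.local.noise_std,
            batch_size=config.local.batch_size,
            iterations=config.local.iterations,
            loss_threshold=config.local.loss_threshold,
            seed=config.local.seed + 1000 * round_index + int(ci),
        )
        client.params, loss = train_local(global_params, client.shard, local_cfg)
        client.bytes_sent += per_transfer  # uplink: client -> server
        locals_.append(client.params)
        counts.append(client.n_samples)
        losses.append(loss)

    new_global = federated_average(locals_, counts)
    weighted_loss = float(np.average(losses, weights=counts))
    log = RoundLog(
        round_index=round_index,
        participants=[clients[int(ci)].client_id for ci in chosen],
        mean_loss=weighted_loss,
        bytes_up=n_part * per_transfer,
        bytes_down=n_part * per_transfer,
    )
    return new_global, log


def run_federated(
    initial_params: BiLSTMParams,
    clients: list[ClientState],
    config: FederatedConfig,
) -> tuple[BiLSTMParams, list[RoundLog]]:
    """Iterate rounds, stopping early when weighted mean loss < threshold."""
    rng = np.random.default_rng(config.seed)
    global_params = initial_params
    logs: list[RoundLog] = []
    for rd in range(config.rounds):
        global_params, log = run_round(global_params, clients, config, rd, rng)
        logs.append(log)
        if log.mean_loss < config.loss_threshold:
            logger.info(
                "round %d: loss %.4g below threshold %.4g, stopping",
                rd,
                log.mean_loss,
                config.loss_threshold,
            )
            break
    return global_params, logs


# ---------------------------------------------------------------------------
# Communication accounting
# ---------------------------------------------------------------------------


@dataclass
class CommunicationReport:
    total_bytes_up: int
    total_bytes_down: int
    raw_dataset_bytes: int
    uplink_to_raw_ratio: float
    rounds: int


def raw_dataset_bytes(n_records: int, n_channels: int, bytes_per_value: int = 4) -> int:
    """Size of the raw sensor stream a centralised design would upload."""
    return n_records * n_channels * bytes_per_value


def communication_report(
    logs: list[RoundLog], raw_bytes: int
) -> CommunicationReport:
    """Totals plus the uplink/raw ratio (the federated saving when < 1).

    Zero rounds run is legal and reports zero bytes.
    """
    if raw_bytes <= 0:
        raise ValidationError("raw_dataset_bytes must be positive")
    up = sum(l.bytes_up for l in logs)
    down = sum(l.bytes_down for l in logs)
    return CommunicationReport(
        total_bytes_up=up,
        total_bytes_down=down,
        raw_dataset_bytes=raw_bytes,
        uplink_to_raw_ratio=up / raw_bytes,
        rounds=len(logs),
    )


def write_round_logs(logs: list[RoundLog], path) -> None:
    """CSV: round,clients,mean_loss,bytes_up,bytes_down."""
    pd.DataFrame(
        [
            [l.round_index, ";".join(l.participants), l.mean_loss, l.bytes_up, l.bytes_down]
            for l in logs
        ],
        columns=["round", "clients", "mean_loss", "bytes_up", "bytes_down"],
    ).to_csv(path, index=False)
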
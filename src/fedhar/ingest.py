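"""Data model, record I/O, cleaning, windowing, feature extraction and splitting.

The on-disk interchange format is a plain CSV of sensor records with the
header ``timestamp,subject_id,position,ch0,...,chK,label`` (label may be
empty), one row per timestamped multi-channel observation.  Subject context
(height, weight, gender, age) and device context (intensity, inclination,
position) live in separate CSVs keyed by subject/device id.

Windows are half-open index intervals ``[s, s + window_len)`` over each
(subject, position) stream, trailing partial windows dropped.  Features are
a fixed, documented ordering of per-channel summary statistics followed by
context scalars, truncated to the requested count (4..45).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("fedhar")

#: Vocabulary of on-body device positions.
POSITIONS = ("arm", "thigh", "head", "shin", "waist", "chest")

#: Label provenance states for a window.
PROVENANCE = ("ground_truth", "propagated", "none")

MIN_FEATURES = 4
MAX_FEATURES = 45

#: Per-channel summary statistics, in feature order.
CHANNEL_STATS = ("mean", "std", "min", "max", "energy")

#: Context scalars appended after all channel statistics, in feature order.
CONTEXT_FEATURES = (
    "height_cm",
    "weight_kg",
    "age_years",
    "gender_code",
    "intensity",
    "inclination",
    "position_code",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; carries the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped multi-channel observation from a worn device.

    ``channels`` has constant length within a dataset; missing channel
    values are NaN until :func:`clean_records` interpolates them.
    """

    timestamp: float
    subject_id: str
    position: str
    channels: tuple[float, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValidationError(
                f"unknown position {self.position!r}; expected one of {POSITIONS}"
            )


@dataclass(frozen=True)
class PersonContext:
    """Subject context tuple: height (cm), weight (kg), gender, age (years)."""

    height: float
    weight: float
    gender: str
    age: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0 or self.age <= 0:
            raise ValidationError("height, weight and age must be positive")


@dataclass(frozen=True)
class SensorContext:
    """Device context: light intensity, inclination (degrees), location."""

    intensity: float
    inclination: float
    location: str

    def __post_init__(self) -> None:
        if self.location not in POSITIONS:
            raise ValidationError(
                f"unknown location {self.location!r}; expected one of {POSITIONS}"
            )


@dataclass
class Window:
    """A fixed-length segment of one (subject, position) stream.

    ``samples`` is a (time, channels) matrix; ``features`` the derived
    vector; ``label_provenance`` is ``none`` iff ``label`` is absent.
    """

    window_id: str
    subject_id: str
    position: str
    samples: np.ndarray
    features: np.ndarray | None = None
    label: str | None = None
    label_provenance: str = "none"

    def __post_init__(self) -> None:
        if self.label_provenance not in PROVENANCE:
            raise ValidationError(f"bad provenance {self.label_provenance!r}")
        if (self.label is None) != (self.label_provenance == "none"):
            raise ValidationError("provenance must be 'none' iff label is absent")


@dataclass
class Dataset:
    """Windows plus subject/device context and a train/val/test assignment."""

    windows: list[Window]
    person_contexts: dict[str, PersonContext] = field(default_factory=dict)
    device_registry: dict[str, SensorContext] = field(default_factory=dict)
    split: dict[str, str] = field(default_factory=dict)  # window_id -> subset

    def subset(self, name: str) -> list[Window]:
        return [w for w in self.windows if self.split.get(w.window_id) == name]


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------


def _n_channels_from_header(columns: list[str]) -> int:
    chans = [c for c in columns if c.startswith("ch") and c[2:].isdigit()]
    if sorted(int(c[2:]) for c in chans) != list(range(len(chans))):
        raise ParseError(f"channel columns not contiguous: {chans}")
    return len(chans)


def write_records(records: list[SensorRecord], path) -> None:
    """Write records to CSV (``timestamp,subject_id,position,ch*,label``)."""
    n_ch = len(records[0].channels) if records else 0
    cols = ["timestamp", "subject_id", "position"] + [f"ch{i}" for i in range(n_ch)]
    rows = []
    for r in records:
        if len(r.channels) != n_ch:
            raise ValidationError("channel length varies across records")
        rows.append(
            [r.timestamp, r.subject_id, r.position, *r.channels, r.label or ""]
        )
    df = pd.DataFrame(rows, columns=cols + ["label"])
    df.to_csv(path, index=False)


def read_records(path) -> list[SensorRecord]:
    """Read records from CSV; malformed rows raise :class:`ParseError`."""
    df = pd.read_csv(path, dtype={"subject_id": str, "label": str})
    n_ch = _n_channels_from_header(list(df.columns))
    records: list[SensorRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # 1-based, after header
        try:
            ts = float(getattr(row, "timestamp"))
            chans = tuple(float(getattr(row, f"ch{c}")) for c in range(n_ch))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        label = getattr(row, "label", None)
        if label is None or (isinstance(label, float) and np.isnan(label)):
            label = None
        elif isinstance(label, str) and not label.strip():
            label = None
        records.append(
            SensorRecord(ts, str(row.subject_id), str(row.position), chans, label)
        )
    return records


def write_contexts(contexts: dict[str, PersonContext], path) -> None:
    df = pd.DataFrame(
        [
            [sid, c.height, c.weight, c.gender, c.age]
            for sid, c in contexts.items()
        ],
        columns=["subject_id", "height_cm", "weight_kg", "gender", "age"],
    )
    df.to_csv(path, index=False)


def read_contexts(path) -> dict[str, PersonContext]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return {
        str(r.subject_id): PersonContext(
            float(r.height_cm), float(r.weight_kg), str(r.gender), int(r.age)
        )
        for r in df.itertuples(index=False)
    }


def write_devices(devices: dict[str, SensorContext], path) -> None:
    df = pd.DataFrame(
        [[did, d.location, d.intensity, d.inclination] for did, d in devices.items()],
        columns=["device_id", "position", "intensity", "inclination"],
    )
    df.to_csv(path, index=False)


def read_devices(path) -> dict[str, SensorContext]:
    df = pd.read_csv(path, dtype={"device_id": str})
    return {
        str(r.device_id): SensorContext(
            float(r.intensity), float(r.inclination), str(r.position)
        )
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean_records(records: list[SensorRecord]) -> list[SensorRecord]:
    """Deduplicate, coerce and impute.

    Exact-duplicate rows (identical after numeric coercion) are dropped
    keeping the first occurrence and preserving input order.  Missing (NaN)
    channel values are filled by per-channel linear interpolation over the
    time-ordered (subject, position) stream, boundary gaps by nearest value.
    A stream whose channel is entirely missing is an error.
    """
    seen: set[tuple] = set()
    deduped: list[SensorRecord] = []
    for r in records:
        # NaN != NaN, so map missing cells to a sentinel for the dedup key
        chan_key = tuple(None if np.isnan(v) else v for v in r.channels)
        key = (r.timestamp, r.subject_id, r.position, chan_key, r.label)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(r)

    # group indices by stream, in input order
    streams: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(deduped):
        streams.setdefault((r.subject_id, r.position), []).append(i)

    out = list(deduped)
    for (sid, pos), idx in streams.items():
        order = sorted(idx, key=lambda i: deduped[i].timestamp)
        mat = np.array([deduped[i].channels for i in order], dtype=float)
        if not np.isnan(mat).any():
            continue
        for c in range(mat.shape[1]):
            col = mat[:, c]
            if np.isnan(col).all():
                raise ValidationError(
                    f"stream (subject={sid}, position={pos}) channel {c} entirely missing"
                )
        filled = (
            pd.DataFrame(mat)
            .interpolate(method="linear", limit_direction="both", axis=0)
            .to_numpy()
        )
        for j, i in enumerate(order):
            out[i] = replace(deduped[i], channels=tuple(filled[j]))
    return out


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def window_id_for(subject_id: str, position: str, start: int) -> str:
    """Canonical window identifier (shared with the synthetic generator)."""
    return f"{subject_id}|{position}|{start}"


def segment_windows(
    records: list[SensorRecord], window_len: int, stride: int
) -> list[Window]:
    """Cut half-open windows [s, s+window_len) per (subject, position) stream.

    Streams are time-ordered; trailing partial windows are dropped.  A
    window's label is the stream's modal record label inside the window if
    every labeled record agrees, else None (mixed windows stay unlabeled).
    """
    if window_len < 1 or stride < 1:
        raise ValidationError("window_len and stride must be >= 1")
    streams: dict[tuple[str, str], list[SensorRecord]] = {}
    for r in records:
        streams.setdefault((r.subject_id, r.position), []).append(r)

    windows: list[Window] = []
    any_fit = False
    for (sid, pos), recs in streams.items():
        recs = sorted(recs, key=lambda r: r.timestamp)
        n = len(recs)
        if n < window_len:
            continue
        any_fit = True
        mat = np.array([r.channels for r in recs], dtype=float)
        for start in range(0, n - window_len + 1, stride):
            seg = recs[start : start + window_len]
            labels = {r.label for r in seg if r.label is not None}
            label = labels.pop() if len(labels) == 1 else None
            windows.append(
                Window(
                    window_id=window_id_for(sid, pos, start),
                    subject_id=sid,
                    position=pos,
                    samples=mat[start : start + window_len],
                    label=label,
                    label_provenance="ground_truth" if label else "none",
                )
            )
    if not any_fit and streams:
        logger.warning(
            "window_len=%d longer than every stream; no windows produced", window_len
        )
    return windows


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def full_feature_vector(
    window: Window,
    person_context: PersonContext | None = None,
    sensor_context: SensorContext | None = None,
) -> np.ndarray:
    """All features in fixed order: per channel mean, sd, min, max, energy
    (mean of squares); then height, weight, age, gender code, intensity,
    inclination, position code.  Missing context contributes zeros."""
    x = np.asarray(window.samples, dtype=float)
    per_channel = np.stack(
        [
            x.mean(axis=0),
            x.std(axis=0),
            x.min(axis=0),
            x.max(axis=0),
            (x**2).mean(axis=0),
        ],
        axis=1,
    ).ravel()  # channel-major: ch0 stats, ch1 stats, ...
    pc = person_context
    sc = sensor_context
    gender_code = 0.0
    if pc is not None:
        gender_code = 1.0 if pc.gender.lower().startswith("f") else 0.0
    context = np.array(
        [
            pc.height if pc else 0.0,
            pc.weight if pc else 0.0,
            float(pc.age) if pc else 0.0,
            gender_code,
            sc.intensity if sc else 0.0,
            sc.inclination if sc else 0.0,
            float(POSITIONS.index(window.position)),
        ]
    )
    return np.concatenate([per_channel, context])


def extract_features(
    window: Window,
    person_context: PersonContext | None,
    sensor_context: SensorContext | None,
    feature_count: int,
) -> np.ndarray:
    """First ``feature_count`` entries (4..45) of the fixed feature order."""
    if not MIN_FEATURES <= feature_count <= MAX_FEATURES:
        raise ValidationError(
            f"feature_count must be in [{MIN_FEATURES}, {MAX_FEATURES}], got {feature_count}"
        )
    full = full_feature_vector(window, person_context, sensor_context)
    if feature_count > full.size:
        raise ValidationError(
            f"feature_count={feature_count} exceeds the {full.size} features "
            f"available with {window.samples.shape[1]} channels"
        )
    return full[:feature_count]


def featurize_dataset(dataset: Dataset, feature_count: int) -> Dataset:
    """Attach feature vectors to every window in place; returns the dataset."""
    for w in dataset.windows:
        pc = dataset.person_contexts.get(w.subject_id)
        sc = next(
            (d for d in dataset.device_registry.values() if d.location == w.position),
            None,
        )
        w.features = extract_features(w, pc, sc, feature_count)
    return dataset


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_dataset(
    dataset: Dataset,
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20),
    seed: int = 0,
) -> Dataset:
    """Assign windows to train/validation/test uniformly at random.

    Sizes use floors computed from the test fraction first:
    ``n_test = floor(f_test * N)``, ``n_val = floor(f_val * N)``, the
    remainder trains — the convention under which 13112 windows yield a
    2622-window test split at 65/15/20.
    """
    if any(f <= 0 for f in fractions):
        raise ValidationError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset.windows)
    if n < 3:
        raise ValidationError(f"need at least 3 windows to split, got {n}")
    n_test = int(np.floor(fractions[2] * n))
    n_val = int(np.floor(fractions[1] * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        wid = dataset.windows[idx].window_id
        if rank < n_test:
            assignment[wid] = "test"
        elif rank < n_test + n_val:
            assignment[wid] = "validation"
        else:
            assignment[wid] = "train"
    dataset.split = assignment
    return dataset


def split_sizes(n: int, fractions=(0.65, 0.15, 0.20)) -> tuple[int, int, int]:
    """(train, validation, test) sizes for an index of ``n`` windows."""
    if n < 3:
        raise ValidationError(f"need at least 3 windows to split, got {n}")
    n_test = int(np.floor(fractions[2] * n))
    n_val = int(np.floor(fractions[1] * n))
    return n - n_val - n_test, n_val, n_test
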
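"""Synthetic wearable-sensor data with controllable cluster structure.

Emulates a multi-subject activity-recognition study: a panel of subjects
(heights ~ N(162.1, 7.7) cm, weights ~ N(75.3, 12.5) kg, ages uniform on
17..65, genders balanced) wearing devices at six on-body positions, each
producing multi-channel streams.  Every activity class k drives all
channels with a class-keyed sinusoid amp_k * sin(2*pi*freq_k*t + phase_c)
plus Gaussian noise; distinct class frequencies are the separability knob.
The signal's time base restarts at each window boundary, so with zero noise
every window of a class is an exact repeat — within-class feature distance
is identically zero, which makes downstream label-propagation behaviour
analytically predictable.

A configurable fraction of windows (0 to 0.999) has its labels hidden from
the pipeline; the ground truth retains them for evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ingest import (
    POSITIONS,
    Dataset,
    PersonContext,
    SensorContext,
    SensorRecord,
    ValidationError,
    window_id_for,
)

#: Daily activities modelled (falls are out of scope).
DEFAULT_ACTIVITIES = (
    "standing",
    "sitting",
    "lying",
    "climbing_up",
    "climbing_down",
    "walking",
    "jogging",
)

# Population statistics the subject generator draws from.
HEIGHT_MEAN, HEIGHT_SD = 162.1, 7.7
WEIGHT_MEAN, WEIGHT_SD = 75.3, 12.5
AGE_MIN, AGE_MAX = 17, 65


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults are the reference study scenario."""

    n_subjects: int = 15
    activities: tuple[str, ...] = DEFAULT_ACTIVITIES
    positions: tuple[str, ...] = POSITIONS
    sampling_rate: float = 50.0  # Hz
    segment_seconds: float = 3.0
    windows_per_subject_activity: int = 2
    n_channels: int = 3
    class_freq: tuple[float, ...] = ()  # Hz per class; default 1..n Hz
    class_amp: tuple[float, ...] = ()  # unitless; default 1 + k/4
    noise_std: float = 0.05
    unlabeled_fraction: float = 0.7
    stratified_mask: bool = False
    duplicate_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.unlabeled_fraction <= 0.999:
            raise ValidationError(
                f"unlabeled_fraction must be in [0, 0.999], got {self.unlabeled_fraction}"
            )
        for name in ("n_subjects", "windows_per_subject_activity", "n_channels"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not self.activities or not self.positions:
            raise ValidationError("need at least one activity and one position")
        freqs = self.freqs()
        if len(set(freqs)) != len(freqs):
            raise ValidationError("class_freq entries must be pairwise distinct")
        if len(freqs) != len(self.activities):
            raise ValidationError("class_freq length must match activities")

    def freqs(self) -> tuple[float, ...]:
        if self.class_freq:
            return self.class_freq
        return tuple(float(k + 1) for k in range(len(self.activities)))

    def amps(self) -> tuple[float, ...]:
        if self.class_amp:
            return self.class_amp
        return tuple(1.0 + 0.25 * k for k in range(len(self.activities)))

    @property
    def window_len(self) -> int:
        return int(round(self.segment_seconds * self.sampling_rate))

    @property
    def n_windows(self) -> int:
        return (
            self.n_subjects
            * len(self.activities)
            * len(self.positions)
            * self.windows_per_subject_activity
        )


@dataclass
class GroundTruth:
    """True label per window id plus the set of windows hidden from the pipeline."""

    labels: dict[str, str]
    mask: set[str] = field(default_factory=set)

    @property
    def n_windows(self) -> int:
        return len(self.labels)


def generate_subjects(n: int, seed: int) -> dict[str, PersonContext]:
    """Draw a subject panel from the modelled population, keyed s00, s01, ...

    Heights ~ N(162.1, 7.7) cm, weights ~ N(75.3, 12.5) kg, integer ages
    uniform on [17, 65], genders alternating (balanced).  Deterministic
    given the seed.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    heights = rng.normal(HEIGHT_MEAN, HEIGHT_SD, size=n)
    weights = rng.normal(WEIGHT_MEAN, WEIGHT_SD, size=n)
    ages = rng.integers(AGE_MIN, AGE_MAX + 1, size=n)
    return {
        f"s{i:02d}": PersonContext(
            height=float(heights[i]),
            weight=float(max(weights[i], 1.0)),
            gender="male" if i % 2 == 0 else "female",
            age=int(ages[i]),
        )
        for i in range(n)
    }


def make_device_registry(positions=POSITIONS) -> dict[str, SensorContext]:
    """One device per position with fixed, distinct context scalars."""
    return {
        f"w{i + 1}": SensorContext(
            intensity=100.0 + 25.0 * i, inclination=15.0 * i, location=pos
        )
        for i, pos in enumerate(positions)
    }


def generate_dataset(config: SyntheticConfig) -> tuple[list[SensorRecord], GroundTruth]:
    """Generate records and ground truth under the configured scenario.

    One stream per (subject, position): the subject performs each activity
    for ``windows_per_subject_activity`` consecutive windows, blocks
    concatenated in activity order with a continuous timestamp axis.  Labels
    of a seeded uniform (or per-class stratified) sample of windows are
    blanked; ground truth keeps them all.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.window_len
    freqs, amps = config.freqs(), config.amps()
    phases = np.pi * np.arange(config.n_channels) / 4.0
    t_local = np.arange(wl) / config.sampling_rate  # time restarts per window

    truth_labels: dict[str, str] = {}
    records: list[SensorRecord] = []
    subjects = [f"s{i:02d}" for i in range(config.n_subjects)]
    for sid in subjects:
        for pos in config.positions:
            start = 0
            for k, act in enumerate(config.activities):
                base = np.stack(
                    [
                        amps[k] * np.sin(2 * np.pi * freqs[k] * t_local + ph)
                        for ph in phases
                    ],
                    axis=1,
                )  # (wl, channels)
                for _ in range(config.windows_per_subject_activity):
                    block = base
                    if config.noise_std > 0:
                        block = base + rng.normal(
                            0.0, config.noise_std, size=base.shape
                        )
                    truth_labels[window_id_for(sid, pos, start)] = act
                    for i in range(wl):
                        records.append(
                            SensorRecord(
                                timestamp=(start + i) / config.sampling_rate,
                                subject_id=sid,
                                position=pos,
                                channels=tuple(block[i]),
                                label=act,
                            )
                        )
                    start += wl

    mask = _choose_mask(truth_labels, config, rng)
    if mask:
        masked_ranges = {
            (wid.split("|")[0], wid.split("|")[1], int(wid.split("|")[2]))
            for wid in mask
        }
        hidden = []
        for r in records:
            s = int(round(r.timestamp * config.sampling_rate))
            w_start = (s // wl) * wl
            if (r.subject_id, r.position, w_start) in masked_ranges:
                hidden.append(replace(r, label=None))
            else:
                hidden.append(r)
        records = hidden
    return records, GroundTruth(labels=truth_labels, mask=mask)


def _choose_mask(
    truth_labels: dict[str, str], config: SyntheticConfig, rng: np.random.Generator
) -> set[str]:
    wids = list(truth_labels)
    n_hide = _round_half_up(config.unlabeled_fraction * len(wids))
    if n_hide == 0:
        return set()
    if not config.stratified_mask:
        return set(rng.choice(wids, size=n_hide, replace=False))
    # stratified: proportional per class, remainder filled uniformly
    mask: set[str] = set()
    by_class: dict[str, list[str]] = {}
    for wid, lab in truth_labels.items():
        by_class.setdefault(lab, []).append(wid)
    for lab, group in sorted(by_class.items()):
        k = int(np.floor(config.unlabeled_fraction * len(group)))
        mask.update(rng.choice(group, size=k, replace=False))
    rest = [w for w in wids if w not in mask]
    short = n_hide - len(mask)
    if short > 0:
        mask.update(rng.choice(rest, size=short, replace=False))
    return mask


def inject_defects(
    records: list[SensorRecord],
    duplicate_rate: float,
    missing_rate: float,
    seed: int,
) -> list[SensorRecord]:
    """Return a corrupted copy: blanked channel cells, then duplicated rows.

    Missing cells (NaN) are blanked on the originals first, so each injected
    duplicate is an exact copy of its (possibly blanked) source row and
    deduplication can restore the original row count.  Rates are fractions
    of rows / of channel cells, both in [0, 0.5].
    """
    for name, rate in (("duplicate_rate", duplicate_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 0.5:
            raise ValidationError(f"{name} must be in [0, 0.5], got {rate}")
    rng = np.random.default_rng(seed)
    out = [replace(r) for r in records]
    if missing_rate > 0 and out:
        n_ch = len(out[0].channels)
        blank = rng.random((len(out), n_ch)) < missing_rate
        for i, r in enumerate(out):
            if blank[i].any():
                chans = tuple(
                    np.nan if blank[i, c] else v for c, v in enumerate(r.channels)
                )
                out[i] = replace(r, channels=chans)
    if duplicate_rate > 0 and out:
        n_dup = _round_half_up(duplicate_rate * len(out))
        dup_idx = set(rng.choice(len(out), size=n_dup, replace=False))
        dupped: list[SensorRecord] = []
        for i, r in enumerate(out):
            dupped.append(r)
            if i in dup_idx:
                dupped.append(replace(r))
        out = dupped
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Two-column CSV (window_id, label) plus a 0/1 hidden-mask column."""
    import pandas as pd

    df = pd.DataFrame(
        [[wid, lab, int(wid in truth.mask)] for wid, lab in truth.labels.items()],
        columns=["window_id", "label", "masked"],
    )
    df.to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    import pandas as pd

    df = pd.read_csv(path)
    labels = {str(r.window_id): str(r.label) for r in df.itertuples(index=False)}
    mask = {str(r.window_id) for r in df.itertuples(index=False) if int(r.masked)}
    return GroundTruth(labels=labels, mask=mask)


def build_dataset(config: SyntheticConfig, feature_count: int = 22) -> tuple[Dataset, GroundTruth]:
    """Generate, segment, featurize and wrap into a Dataset in one call."""
    from . import ingest

    records, truth = generate_dataset(config)
    windows = ingest.segment_windows(records, config.window_len, config.window_len)
    ds = Dataset(
        windows=windows,
        person_contexts=generate_subjects(config.n_subjects, config.seed),
        device_registry=make_device_registry(config.positions),
    )
    ingest.featurize_dataset(ds, feature_count)
    return ds, truth
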
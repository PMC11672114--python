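"""Core containers shared across the pipeline.

A :class:`Recording` is a bag of named sampled channels, each with its own
sampling rate and electrode role; PSG and in-ear devices run on different
clocks (256 Hz vs 250 Hz in the study design), so rates are per channel and
nothing here ever resamples.  A :class:`Hypnogram` is one stage label per
30-second epoch.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

#: three-class stage alphabet used throughout the analysis
STAGES3 = ("W", "NREM", "REM")

#: full annotation alphabet as delivered by the scorers
STAGES_FULL = ("W", "N1", "N2", "N3", "REM", "MOVEMENT", "UNKNOWN")

#: labels excluded from every analysis step
EXCLUDED_LABELS = ("MOVEMENT", "UNKNOWN")

#: mapping of 5-class AASM labels onto the merged 3-class alphabet
#: (idempotent: already-merged labels map to themselves)
STAGE_MAP3 = {
    "NREM": "NREM",
    "W": "W",
    "N1": "NREM",
    "N2": "NREM",
    "N3": "NREM",
    "REM": "REM",
    "MOVEMENT": "MOVEMENT",
    "UNKNOWN": "UNKNOWN",
}

#: channel roles
ROLE_SCALP = "scalp-EEG"
ROLE_EOG = "EOG"
ROLE_MASTOID = "mastoid"
ROLE_INEAR = "in-ear"
ROLES = (ROLE_SCALP, ROLE_EOG, ROLE_MASTOID, ROLE_INEAR)


@dataclass
class Recording:
    """Named channels with per-channel sampling rate and role.

    Parameters
    ----------
    channels
        Mapping channel name -> 1-D float array of samples.
    fs
        Mapping channel name -> sampling rate in Hz.
    roles
        Mapping channel name -> one of :data:`ROLES`.
    start_offset
        Wall-clock time (seconds) of this recording's first sample relative
        to the session origin; used by alignment.
    """

    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    roles: dict[str, str]
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        for name, x in self.channels.items():
            self.channels[name] = np.asarray(x, dtype=float)
            if name not in self.fs:
                raise ValueError(f"missing sampling rate for channel {name!r}")
            if self.fs[name] <= 0:
                raise ValueError(f"non-positive sampling rate for {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def duration(self, name: str | None = None) -> float:
        """Duration in seconds of one channel (or the common duration)."""
        if name is not None:
            return len(self.channels[name]) / self.fs[name]
        durs = {n: len(x) / self.fs[n] for n, x in self.channels.items()}
        vals = np.array(list(durs.values()))
        if not np.allclose(vals, vals[0], atol=1.0 / max(self.fs.values())):
            raise ValueError(f"channels differ in duration: {durs}")
        return float(vals[0])

    def copy(self) -> "Recording":
        return Recording(
            {n: x.copy() for n, x in self.channels.items()},
            dict(self.fs),
            dict(self.roles),
            self.start_offset,
        )


@dataclass
class Hypnogram:
    """Sequence of sleep-stage labels, one per scoring epoch."""

    labels: np.ndarray
    epoch_len: float = 30.0
    source: str = "PSG"  # "PSG" or "in-ear"
    scorer: str | int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or len(self.labels) < 1:
            raise ValueError("hypnogram needs at least one epoch label")
        bad = set(self.labels) - set(STAGES_FULL) - set(STAGES3)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def map3(self) -> "Hypnogram":
        """Merge N1/N2/N3 into NREM (idempotent)."""
        mapped = np.array([STAGE_MAP3[l] for l in self.labels], dtype=object)
        return Hypnogram(mapped, self.epoch_len, self.source, self.scorer)

    @property
    def excluded_mask(self) -> np.ndarray:
        """True where the label is MOVEMENT or UNKNOWN."""
        return np.isin(self.labels.astype(str), EXCLUDED_LABELS)


@dataclass
class ScorerPanel:
    """J hypnograms over the same T epochs from the same source."""

    hypnograms: list[Hypnogram]

    def __post_init__(self) -> None:
        if len(self.hypnograms) == 0:
            raise ValueError("panel needs at least one scorer")
        T = len(self.hypnograms[0])
        if any(len(h) != T for h in self.hypnograms):
            raise ValueError("scorers disagree on epoch count")
        src = {h.source for h in self.hypnograms}
        if len(src) > 1:
            raise ValueError(f"panel mixes sources: {src}")

    @property
    def n_scorers(self) -> int:
        return len(self.hypnograms)

    @property
    def n_epochs(self) -> int:
        return len(self.hypnograms[0])

    @property
    def source(self) -> str:
        return self.hypnograms[0].source

    def label_matrix(self) -> np.ndarray:
        """(J, T) object array of labels."""
        return np.stack([h.labels for h in self.hypnograms])

    def usable_mask(self) -> np.ndarray:
        """Epochs where no scorer assigned MOVEMENT/UNKNOWN."""
        return ~np.any(
            np.stack([h.excluded_mask for h in self.hypnograms]), axis=0
        )


@dataclass
class EpochedSignal:
    """Per-channel stacks of non-overlapping fixed-length epochs.

    ``epochs[name]`` has shape (M, epoch_len*fs[name]); channels at
    different rates keep different sample counts but share the epoch count.
    """

    epochs: dict[str, np.ndarray]
    fs: dict[str, float]
    roles: dict[str, str]
    epoch_len: float
    noisy_mask: dict[str, np.ndarray]
    excluded_channels: set[str] = field(default_factory=set)

    @property
    def n_epochs(self) -> int:
        counts = {len(e) for e in self.epochs.values()}
        if len(counts) != 1:
            raise ValueError(f"inconsistent epoch counts: {counts}")
        return counts.pop()

    def good_channels(self) -> list[str]:
        return [n for n in self.epochs if n not in self.excluded_channels]
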
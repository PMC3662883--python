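"""Shared containers and delimited-text I/O for ensemble-state analysis.

Time is always seconds from session start; firing rates are spikes/s.
All on-disk formats are plain delimited text so that every table a stage
writes can be re-read by the stage that consumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 0.5  # s; the analysis bin everything downstream assumes


class EmptyEnsembleError(ValueError):
    """Raised when a filtering step removes every unit."""


@dataclass(frozen=True)
class EpochDefinition:
    """Contiguous baseline / pellet-drop / post partition of a session.

    Each epoch is a half-open ``[start, end)`` interval in seconds.
    """

    baseline: tuple[float, float]
    drop_period: tuple[float, float]
    post: tuple[float, float]

    def __post_init__(self) -> None:
        b, d, p = self.baseline, self.drop_period, self.post
        for lo, hi in (b, d, p):
            if not hi > lo:
                raise ValueError("epoch intervals must have positive length")
        if not (b[1] == d[0] and d[1] == p[0]):
            raise ValueError("epochs must be contiguous: baseline, drop_period, post")

    @property
    def session_start(self) -> float:
        return self.baseline[0]

    @property
    def session_end(self) -> float:
        return self.post[1]

    def epoch_of(self, t: np.ndarray) -> np.ndarray:
        """Label times with 'baseline' / 'drop' / 'post' ('' outside)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        out[(t >= self.baseline[0]) & (t < self.baseline[1])] = "baseline"
        out[(t >= self.drop_period[0]) & (t < self.drop_period[1])] = "drop"
        out[(t >= self.post[0]) & (t < self.post[1])] = "post"
        return out


@dataclass(frozen=True)
class EventSchedule:
    """Pellet-drop and consumption event times, ascending within the session."""

    labels: tuple[str, ...]
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if len(self.labels) != times.size:
            raise ValueError("labels and times length mismatch")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("event times must be ascending")
        bad = set(self.labels) - {"drop", "consume"}
        if bad:
            raise ValueError(f"unknown event labels: {bad}")

    def of(self, label: str) -> np.ndarray:
        mask = np.array([lab == label for lab in self.labels], dtype=bool)
        return self.times[mask]

    @property
    def drop_times(self) -> np.ndarray:
        return self.of("drop")

    @property
    def consume_times(self) -> np.ndarray:
        return self.of("consume")


@dataclass
class SpikeTrainSet:
    """Per-unit spike timestamps with session epoch/event metadata."""

    unit_ids: list[str]
    spikes: list[np.ndarray]  # sorted seconds, strictly within the session
    session_start: float
    session_end: float
    epochs: EpochDefinition | None = None
    events: EventSchedule | None = None

    def __post_init__(self) -> None:
        if len(self.unit_ids) != len(self.spikes):
            raise ValueError("unit_ids and spikes length mismatch")
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for uid, s in zip(self.unit_ids, self.spikes):
            if s.size and (np.any(np.diff(s) < 0)):
                raise ValueError(f"unit {uid}: spike times not sorted")
            if s.size and (s[0] < self.session_start or s[-1] > self.session_end):
                raise ValueError(f"unit {uid}: spikes outside session bounds")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def duration(self) -> float:
        return self.session_end - self.session_start

    def mean_rates(self) -> np.ndarray:
        """Whole-session mean firing rate per unit (spikes/s)."""
        counts = np.array([s.size for s in self.spikes], dtype=float)
        return counts / self.duration


@dataclass
class RateMatrix:
    """N units x T bins of instantaneous firing rates.

    ``t0`` is the session time of the first bin's left edge; bin centers are
    ``t0 + (arange(T) + 0.5) * bin_width``.
    """

    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    t0: float = 0.0
    unit_ids: list[str] = field(default_factory=list)
    epochs: EpochDefinition | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be N x T with T >= 1")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("rates must be finite and non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not self.unit_ids:
            self.unit_ids = [f"u{i}" for i in range(self.values.shape[0])]

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def epoch_bin_mask(self, epoch: str) -> np.ndarray:
        """Boolean mask of bins whose centers fall in the named epoch."""
        if self.epochs is None:
            raise ValueError("RateMatrix carries no epoch definition")
        lo, hi = getattr(self.epochs, "drop_period" if epoch == "drop" else epoch)
        c = self.bin_centers
        return (c >= lo) & (c < hi)


@dataclass
class PosteriorMatrix:
    """Q states x T bins of posterior state probabilities P[Q(t)=i | y(1:T)]."""

    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be Q x T")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("posteriors must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posterior columns must sum to 1")

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_TIME_FMT = "%.6f"
_PROB_FMT = "%.9f"


def write_spikes(path: str | Path, spikes: SpikeTrainSet) -> None:
    rows = [
        (uid, t)
        for uid, s in zip(spikes.unit_ids, spikes.spikes)
        for t in s
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    df.to_csv(path, index=False, float_format=_TIME_FMT)


def read_spikes(
    path: str | Path,
    session_start: float,
    session_end: float,
    epochs: EpochDefinition | None = None,
    events: EventSchedule | None = None,
) -> SpikeTrainSet:
    df = pd.read_csv(path, dtype={"unit_id": str, "time_s": float})
    unit_ids = list(dict.fromkeys(df["unit_id"]))  # first-appearance order
    trains = [
        np.sort(df.loc[df["unit_id"] == uid, "time_s"].to_numpy())
        for uid in unit_ids
    ]
    return SpikeTrainSet(unit_ids, trains, session_start, session_end, epochs, events)


def write_events(path: str | Path, events: EventSchedule) -> None:
    df = pd.DataFrame({"label": events.labels, "time_s": events.times})
    df.to_csv(path, index=False, float_format=_TIME_FMT)


def read_events(path: str | Path) -> EventSchedule:
    df = pd.read_csv(path, dtype={"label": str, "time_s": float})
    return EventSchedule(tuple(df["label"]), df["time_s"].to_numpy())


def write_epochs(path: str | Path, epochs: EpochDefinition) -> None:
    df = pd.DataFrame(
        {
            "epoch": ["baseline", "drop_period", "post"],
            "start_s": [epochs.baseline[0], epochs.drop_period[0], epochs.post[0]],
            "end_s": [epochs.baseline[1], epochs.drop_period[1], epochs.post[1]],
        }
    )
    df.to_csv(path, index=False, float_format=_TIME_FMT)


def read_epochs(path: str | Path) -> EpochDefinition:
    df = pd.read_csv(path).set_index("epoch")
    pair = lambda name: (float(df.loc[name, "start_s"]), float(df.loc[name, "end_s"]))
    return EpochDefinition(pair("baseline"), pair("drop_period"), pair("post"))


def _write_binned(path: Path, values: np.ndarray, bin_width: float, t0: float,
                  row_ids: Sequence[str], fmt: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width={bin_width:.6f} t0={t0:.6f}\n")
        fh.write("row_id," + ",".join(f"b{j}" for j in range(values.shape[1])) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(rid + "," + ",".join(fmt % v for v in row) + "\n")


def _read_binned(path: Path) -> tuple[np.ndarray, float, float, list[str]]:
    with open(path) as fh:
        header = fh.readline().strip()
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    df = pd.read_csv(path, skiprows=1)
    return (
        df.iloc[:, 1:].to_numpy(dtype=float),
        float(meta["bin_width"]),
        float(meta["t0"]),
        [str(r) for r in df.iloc[:, 0]],
    )


def write_rate_matrix(path: str | Path, rates: RateMatrix) -> None:
    _write_binned(Path(path), rates.values, rates.bin_width, rates.t0,
                  rates.unit_ids, "%.6f")


def read_rate_matrix(path: str | Path,
                     epochs: EpochDefinition | None = None) -> RateMatrix:
    values, bw, t0, row_ids = _read_binned(Path(path))
    return RateMatrix(values, bw, t0, row_ids, epochs)


def write_posteriors(path: str | Path, post: PosteriorMatrix) -> None:
    _write_binned(Path(path), post.values, post.bin_width, post.t0,
                  [f"state{i}" for i in range(post.n_states)], _PROB_FMT)


def read_posteriors(path: str | Path) -> PosteriorMatrix:
    values, bw, t0, _ = _read_binned(Path(path))
    # rows were written to 9 decimals; renormalize away rounding residue
    values = values / values.sum(axis=0, keepdims=True)
    return PosteriorMatrix(values, bw, t0)


def write_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=1, default=default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
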
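"""Food ledger, jam log, the transport-efficiency series E, and replicate
averaging.

Transport efficiency after tau steps is

    E(tau) = s * sum_{t<=tau} food(t) / (tau * N0)

where food(t) is the food value deposited into the nest at step t (each
particle is worth max(0, 1 - 0.09 n) after n hand-offs), N0 is the number of
agents and s = 10,000 is a scale constant.  The sum is therefore the cumulative
delivered value F(tau), so E saturates under a constant delivery rate.  An
alternative reading that re-sums the cumulative series is available via
``mode="cumulative"`` for comparison; it grows without bound under sustained
delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_SCALE = 10_000.0
SATURATION_WINDOW = (3000, 5000)   # late-time window over which E stabilizes


@dataclass
class FoodLedger:
    """Append-only record of nest deposits: parallel arrays of step and value."""

    times: list = field(default_factory=list)
    values: list = field(default_factory=list)

    def record(self, t: int, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"deposit value {value} outside [0, 1]")
        self.times.append(int(t))
        self.values.append(float(value))

    def record_many(self, t: int, values: np.ndarray) -> None:
        self.times.extend([int(t)] * len(values))
        self.values.extend(float(v) for v in values)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total(self) -> float:
        return float(np.sum(self.values)) if self.values else 0.0

    def per_step(self, T: int) -> np.ndarray:
        """food(t) for t = 1..T: value deposited at each step (index t-1)."""
        out = np.zeros(T)
        if self.times:
            t = np.asarray(self.times)
            v = np.asarray(self.values)
            keep = t <= T
            np.add.at(out, t[keep] - 1, v[keep])
        return out

    def cumulative(self, T: int) -> np.ndarray:
        """F(tau) for tau = 1..T: total value delivered by step tau."""
        return np.cumsum(self.per_step(T))


@dataclass
class JamLog:
    """Chronological record of jam events (t, site, group size)."""

    events: list = field(default_factory=list)   # tuples (t, site, size)

    def record(self, t: int, site: int, size: int) -> None:
        self.events.append((int(t), int(site), int(size)))

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class EfficiencySeries:
    """E(tau) for tau = 1..T plus the constants that scale it."""

    E: np.ndarray
    s: float
    N0: int

    @property
    def T(self) -> int:
        return self.E.size

    def saturation_mean(self, window: tuple[int, int] = SATURATION_WINDOW) -> float:
        """Mean E over the late-time window (clipped to the series length)."""
        lo, hi = window
        hi = min(hi, self.T)
        lo = min(lo, hi - 1) if hi > 1 else 0
        return float(self.E[lo:hi].mean())


def efficiency_series(
    ledger: FoodLedger,
    T: int,
    s: float = DEFAULT_SCALE,
    N0: int = 100,
    mode: str = "increment",
) -> EfficiencySeries:
    """Compute E(tau) for tau = 1..T from a deposit ledger.

    ``mode="increment"`` (default) treats food(t) as the per-step deposit, so
    the numerator is the cumulative total F(tau).  ``mode="cumulative"`` treats
    food(t) as the running total and sums it again.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if N0 < 1:
        raise ValueError("N0 must be >= 1")
    F = ledger.cumulative(T)
    if mode == "cumulative":
        F = np.cumsum(F)
    elif mode != "increment":
        raise ValueError(f"unknown mode {mode!r}")
    tau = np.arange(1, T + 1)
    return EfficiencySeries(E=s * F / (tau * N0), s=float(s), N0=int(N0))


def total_jam_frequency(log: JamLog) -> int:
    """Total number of jam events over the run (sum of per-step frequencies)."""
    return len(log.events)


def jam_frequency_binned(log: JamLog, bin_width: int, T: int) -> np.ndarray:
    """Jam-event counts in consecutive time bins of width ``bin_width``."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = (T + bin_width - 1) // bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    for t, _site, _size in log.events:
        if 1 <= t <= T:
            counts[(t - 1) // bin_width] += 1
    return counts


@dataclass(frozen=True)
class RunResult:
    """Outcome of one simulation run."""

    config: dict
    seed_path: tuple[int, ...]
    ledger: FoodLedger
    jam_log: JamLog
    efficiency: EfficiencySeries
    counters: dict

    @property
    def T(self) -> int:
        return self.efficiency.T

    @property
    def total_food(self) -> float:
        return self.ledger.total

    @property
    def total_jams(self) -> int:
        return total_jam_frequency(self.jam_log)

    def efficiency_csv(self) -> str:
        F = self.ledger.cumulative(self.T)
        lines = ["t,cumulative_food,E"]
        lines += [
            f"{t},{F[t - 1]:.6g},{self.efficiency.E[t - 1]:.6g}"
            for t in range(1, self.T + 1)
        ]
        return "\n".join(lines) + "\n"

    def jam_csv(self) -> str:
        lines = ["t,site,size"]
        lines += [f"{t},{site},{size}" for t, site, size in self.jam_log.events]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate-averaged series/scalars plus per-replicate values."""

    mean_E: np.ndarray              # element-wise mean over replicates
    per_replicate_E: np.ndarray     # shape (R, T)
    mean_total_jams: float
    per_replicate_jams: np.ndarray  # shape (R,)
    mean_total_food: float

    @property
    def n_replicates(self) -> int:
        return self.per_replicate_E.shape[0]


def average_over_replicates(results: Sequence[RunResult]) -> ReplicateSummary:
    """Element-wise mean of the E series and jam totals across replicates."""
    if not results:
        raise ValueError("no replicates given")
    T = results[0].T
    if any(r.T != T for r in results):
        raise ValueError("replicates have mismatched T")
    per_E = np.stack([r.efficiency.E for r in results])
    jams = np.array([r.total_jams for r in results], dtype=float)
    return ReplicateSummary(
        mean_E=per_E.mean(axis=0),
        per_replicate_E=per_E,
        mean_total_jams=float(jams.mean()),
        per_replicate_jams=jams,
        mean_total_food=float(np.mean([r.total_food for r in results])),
    )
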
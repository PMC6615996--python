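"""Multinomial snapshot likelihood for smFISH-style histograms.

Each observation time t_l contributes an independent multinomial draw of
N_l cells over (m, TS) bins, so

    ln L = sum_l [ ln M_l + sum_w h(w, t_l) ln P(w, t_l) ],

where M_l is the multinomial coefficient of the histogram at t_l (a
theta-independent constant that cancels in Metropolis-Hastings ratios but
matters for comparing evidence consistently across models).  Bin
probabilities coming from a finite Monte Carlo mixture can be exactly zero
at an observed bin; a configurable probability floor keeps the
log-likelihood finite and the number of floored bins is surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SnapshotHistogram",
    "LogLikelihoodValue",
    "log_multinomial_coefficient",
    "log_likelihood",
]


@dataclass
class SnapshotHistogram:
    """Counts of cells per (m, TS) bin at each observation time.

    ``bins[l]`` is a dict mapping ``(m, TS) -> count`` for time
    ``observation_times[l]``.
    """

    observation_times: np.ndarray
    bins: list[dict[tuple[int, int], int]]

    def __post_init__(self):
        self.observation_times = np.asarray(self.observation_times, dtype=float)
        if len(np.unique(self.observation_times)) != len(self.observation_times):
            raise ValueError("observation times must be distinct")
        if len(self.bins) != len(self.observation_times):
            raise ValueError("one bin table per observation time required")
        for table in self.bins:
            for (m, ts), c in table.items():
                if c < 0 or int(c) != c or m < 0 or ts < 0:
                    raise ValueError(f"invalid bin ({m},{ts}) -> {c}")

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([sum(t.values()) for t in self.bins])

    @property
    def total_cells(self) -> int:
        return int(self.n_cells.sum())

    def bin_arrays(self, time_index: int):
        """(m, ts, count) arrays sorted by (m, ts) for one time point."""
        items = sorted(self.bins[time_index].items())
        m = np.array([k[0] for k, _ in items], dtype=np.int64)
        ts = np.array([k[1] for k, _ in items], dtype=np.int64)
        c = np.array([v for _, v in items], dtype=np.int64)
        return m, ts, c

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, table in zip(self.observation_times, self.bins):
            for (m, ts), c in sorted(table.items()):
                rows.append((t, m, ts, c))
        return pd.DataFrame(rows, columns=["time", "m", "TS", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnapshotHistogram":
        required = {"time", "m", "TS", "count"}
        if not required <= set(df.columns):
            raise ValueError(f"histogram table needs columns {sorted(required)}")
        counts = df["count"].to_numpy()
        if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
            raise ValueError("counts must be non-negative integers")
        times = np.sort(df["time"].unique())
        bins = []
        for t in times:
            sub = df[df["time"] == t]
            table: dict[tuple[int, int], int] = {}
            for _, row in sub.iterrows():
                key = (int(row["m"]), int(row["TS"]))
                table[key] = table.get(key, 0) + int(row["count"])
            bins.append(table)
        return cls(times, bins)

    @classmethod
    def from_tsv(cls, path) -> "SnapshotHistogram":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class LogLikelihoodValue:
    total: float
    per_time: np.ndarray
    include_multinomial: bool
    n_floored: int = 0
    log_multinomial: float = 0.0


def log_multinomial_coefficient(counts) -> float:
    """ln( N! / prod_w h_w! ) via log-gamma."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    N = counts.sum()
    return float(gammaln(N + 1.0) - gammaln(counts + 1.0).sum())


def log_likelihood(
    h: SnapshotHistogram,
    probabilities,
    include_multinomial: bool = True,
    floor: float = 1e-12,
) -> LogLikelihoodValue:
    """Snapshot log-likelihood of per-bin probabilities against a histogram.

    ``probabilities[l]`` must align with ``h.bin_arrays(l)`` (sorted bins).
    Probabilities below ``floor`` are clipped before the log; the number of
    floored observed bins is reported.
    """
    L = len(h.observation_times)
    if len(probabilities) != L:
        raise ValueError("need one probability vector per observation time")
    per_time = np.zeros(L)
    log_mult = 0.0
    n_floored = 0
    for l in range(L):
        _, _, counts = h.bin_arrays(l)
        p = np.asarray(probabilities[l], dtype=float)
        if p.shape != counts.shape:
            raise ValueError(f"missing bin probabilities at time index {l}")
        n_floored += int(np.count_nonzero((p < floor) & (counts > 0)))
        term = float(np.dot(counts, np.log(np.clip(p, floor, None))))
        if include_multinomial:
            lm = log_multinomial_coefficient(counts)
            log_mult += lm
            term += lm
        per_time[l] = term
    return LogLikelihoodValue(
        total=float(per_time.sum()),
        per_time=per_time,
        include_multinomial=include_multinomial,
        n_floored=n_floored,
        log_multinomial=log_mult,
    )
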
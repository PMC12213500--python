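"""Frequency representations of descriptor distributions.

Continuous descriptors (MW, logP) are histogrammed with the bin width
chosen by the Shimazaki-Shinomoto cost criterion; discrete descriptors
(HBA, HBD, nRotB, nArR) are tallied exactly at every integer from zero
to their observed maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when the data cannot support a histogram (zero range, too few values)."""


@dataclass
class FrequencyTable:
    """Values and their frequencies for one descriptor.

    ``xs`` are bin centers for continuous data, the integers 0..max for
    discrete data.  ``sum(counts) == n_total`` always holds.
    """

    xs: np.ndarray
    counts: np.ndarray
    kind: str  # "continuous" | "discrete"
    n_total: int
    bin_width: float | None = None

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.xs.shape != self.counts.shape:
            raise ValueError("xs and counts must have the same length")
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if int(round(self.counts.sum())) != self.n_total:
            raise ValueError("counts do not sum to n_total")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"value": self.xs, "count": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str) -> "FrequencyTable":
        import pandas as pd

        df = pd.read_csv(path)
        xs = df["value"].to_numpy(float)
        counts = df["count"].to_numpy(float)
        width = float(xs[1] - xs[0]) if kind == "continuous" and len(xs) > 1 else None
        return cls(xs, counts, kind, int(round(counts.sum())), bin_width=width)


def _ss_cost(values: np.ndarray, n_bins: int, lo: float, hi: float) -> float:
    """Shimazaki-Shinomoto cost C(delta) = (2*kbar - v) / delta**2 for a
    partition of [lo, hi] into ``n_bins`` equal bins (last bin closed)."""
    delta = (hi - lo) / n_bins
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    kbar = counts.mean()
    v = counts.var()  # biased (1/N) variance, as the criterion requires
    return (2.0 * kbar - v) / delta**2


def optimal_bin_width(
    values, candidate_range: tuple[int, int] | None = None
) -> tuple[float, int]:
    """Select the histogram bin width minimising the Shimazaki-Shinomoto cost.

    Every candidate bin count ``N`` in ``candidate_range`` (default
    ``[2, min(200, n)]``) partitions ``[min, max]`` into equal bins; the
    cost ``C = (2*kbar - v)/delta**2`` (``kbar``, ``v`` the mean and biased
    variance of the bin counts) is evaluated and the minimising width
    returned.  Ties break toward smaller ``N``.

    Returns
    -------
    (bin_width, bin_count)
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateInputError("need at least 2 values to choose a bin width")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise DegenerateInputError("all values identical: zero range")
    if candidate_range is None:
        candidate_range = (2, min(200, values.size))
    n_min, n_max = int(candidate_range[0]), int(candidate_range[1])
    if not (2 <= n_min <= n_max):
        raise ValueError(f"invalid candidate range {candidate_range}")

    best_n, best_cost = None, np.inf
    for n in range(n_min, n_max + 1):
        cost = _ss_cost(values, n, lo, hi)
        if cost < best_cost:  # strict: ties keep the earlier (smaller) N
            best_n, best_cost = n, cost
    return (hi - lo) / best_n, best_n


def continuous_frequencies(
    values, candidate_range: tuple[int, int] | None = None
) -> FrequencyTable:
    """Optimal-width histogram of a continuous descriptor, xs at bin centers."""
    values = np.asarray(values, dtype=float)
    width, n_bins = optimal_bin_width(values, candidate_range)
    lo, hi = float(values.min()), float(values.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)  # last bin closed: max counted
    centers = (edges[:-1] + edges[1:]) / 2.0
    return FrequencyTable(centers, counts, "continuous", values.size, bin_width=width)


def integer_frequencies(values) -> FrequencyTable:
    """Exact multiplicities of a non-negative integer descriptor.

    ``xs`` spans every integer from 0 to ``max(values)`` inclusive, so
    unobserved intermediate values appear with count zero.
    """
    values = np.asarray(values)
    if values.size < 1:
        raise DegenerateInputError("need at least 1 value")
    if np.any(values < 0):
        raise ValueError("negative value in integer descriptor")
    ints = values.astype(int)
    if not np.array_equal(ints, values.astype(float)):
        raise ValueError("non-integer value in integer descriptor")
    counts = np.bincount(ints, minlength=int(ints.max()) + 1)
    xs = np.arange(counts.size)
    return FrequencyTable(xs, counts, "discrete", int(values.size))
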
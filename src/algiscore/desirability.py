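"""The per-descriptor desirability function and its fit.

The desirability of a descriptor value x is the four-parameter
asymmetric peak

    df(x) = o + a * exp(-exp(-t) - t + 1),    t = (x - b) / c

(a Gumbel-shaped bump: baseline o, peak height o + a reached exactly at
x = b, width/asymmetry scale c; both tails decay back to o).  Fitting
normalises the frequency counts of a reference set to peak height 1 and
least-squares-fits (o, a, b, c) with a deterministic multi-start grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

from .binning import FrequencyTable


class InsufficientDataError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass
class DesirabilityParams:
    """Fitted coefficients of the desirability curve for one descriptor."""

    o: float
    a: float
    b: float
    c: float
    descriptor: str
    fit_rmse: float = float("nan")
    fit_range: tuple[float, float] = (float("nan"), float("nan"))
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.c == 0:
            raise ValueError("c must be nonzero")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_range"] = list(self.fit_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesirabilityParams":
        d = dict(d)
        d["fit_range"] = tuple(d.get("fit_range", (float("nan"), float("nan"))))
        return cls(**d)


def evaluate_desirability(params: DesirabilityParams, x) -> np.ndarray | float:
    """Closed-form desirability at x (scalar or array).  Total function:
    defined for all real x, maximum o + a at x = b, tails -> o."""
    t = (np.asarray(x, dtype=float) - params.b) / params.c
    # exp(-exp(-t) - t + 1); guard the inner exp against overflow for t << 0
    with np.errstate(over="ignore"):
        val = params.o + params.a * np.exp(-np.exp(-t) - t + 1.0)
    val = np.where(np.isfinite(val), val, params.o)
    return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val


def _curve(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    o, a, b, c = theta
    t = (x - b) / c
    with np.errstate(over="ignore"):
        y = o + a * np.exp(-np.exp(-t) - t + 1.0)
    return np.where(np.isfinite(y), y, o)


def fit_desirability(freq: FrequencyTable, descriptor: str) -> DesirabilityParams:
    """Fit (o, a, b, c) to a frequency table by bounded least squares.

    Counts on a raw frequency scale (max > 1) are first scaled so the
    tallest bin equals 1, making the fitted curve a [0, 1]-valued
    desirability; inputs already on the [0, 1] scale are fitted as-is.
    A fixed grid of starts
    (b in {mode, mean}; c in {+/- sigma/2, +/- sigma}; o0 in {0, min count})
    is tried and the best residual wins, ties going to grid order, so the
    fit is deterministic.  Negative c captures left-skewed shapes.
    """
    xs = np.asarray(freq.xs, dtype=float)
    counts = np.asarray(freq.counts, dtype=float)
    if xs.size < 5:
        raise InsufficientDataError(
            f"{descriptor}: need >= 5 frequency points, got {xs.size}")
    if counts.sum() <= 0:
        raise InsufficientDataError(f"{descriptor}: all counts zero")

    cmax = counts.max()
    y = counts / cmax if cmax > 1.0 else counts.copy()
    lo, hi = float(xs.min()), float(xs.max())
    rng = hi - lo
    if rng == 0:
        raise InsufficientDataError(f"{descriptor}: zero descriptor range")

    w = counts / counts.sum()
    mean = float(np.sum(w * xs))
    sigma = float(np.sqrt(np.sum(w * (xs - mean) ** 2))) or rng / 4.0
    mode = float(xs[int(np.argmax(counts))])
    ymin = float(y.min())

    b_lo, b_hi = lo - 0.1 * rng, hi + 0.1 * rng
    c_min, c_max = 1e-6 * rng, 10.0 * rng

    best = None
    for b0 in (mode, mean):
        for c0 in (sigma / 2.0, -sigma / 2.0, sigma, -sigma):
            for o0 in (0.0, ymin):
                a0 = max(1.0 - o0, 1e-3)
                if c0 > 0:
                    c_bounds = (c_min, c_max)
                    c_start = min(max(c0, c_min), c_max)
                else:
                    c_bounds = (-c_max, -c_min)
                    c_start = min(max(c0, -c_max), -c_min)
                theta0 = [min(o0, 0.5), min(a0, 1.2), b0, c_start]
                try:
                    res = least_squares(
                        lambda th: _curve(th, xs) - y,
                        theta0,
                        bounds=([0.0, 1e-8, b_lo, c_bounds[0]],
                                [0.5, 1.2, b_hi, c_bounds[1]]),
                        method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    )
                except Exception:
                    continue
                if best is None or res.cost < best.cost - 1e-15:
                    best = res
    if best is None:
        raise FitFailureError(f"{descriptor}: optimiser failed on every start")

    o, a, b, c = best.x
    rmse = float(np.sqrt(np.mean((_curve(best.x, xs) - y) ** 2)))
    return DesirabilityParams(
        o=float(o), a=float(a), b=float(b), c=float(c),
        descriptor=descriptor, fit_rmse=rmse, fit_range=(lo, hi),
        kind=freq.kind,
    )
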
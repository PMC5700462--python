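"""Dwell-time statistics: lifetimes, transition probabilities, occupancies.

From an idealized :class:`~smfet.models.StatePath` this module extracts
direction-resolved dwell times (the duration of a sojourn in state ``i``
grouped by the destination state ``j``), fits single-exponential lifetimes,
and assembles the transition-probability / mean-lifetime matrix together with
time-weighted state occupancies.

Censoring convention: the first and last sojourns of a path have no observed
predecessor/successor and are dropped from dwell statistics, but occupancy is
a whole-trace time fraction and uses every sojourn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .models import STATES, ParameterError, StatePath

logger = logging.getLogger(__name__)


class DwellRecord(NamedTuple):
    """One completed, direction-resolved sojourn."""

    state: str
    duration: float  # ms
    next_state: str


class InsufficientDwellsError(ValueError):
    """Raised when too few dwells are available for a lifetime fit."""

    def __init__(self, n: int, floor: int):
        self.n = n
        self.floor = floor
        super().__init__(f"need >= {floor} dwells for a lifetime fit, got {n}")


@dataclass
class ExponentialFit:
    """Single-exponential lifetime estimate.

    ``tau`` is the maximum-likelihood mean (the sample mean for exponential
    data); ``ci`` a nonparametric bootstrap percentile interval; ``tau_lsq``
    a binned least-squares fit of ``A exp(-t/tau)`` to the dwell histogram,
    kept as a diagnostic cross-check of the MLE.
    """

    tau: float
    ci: tuple[float, float]
    n: int
    tau_lsq: float | None = None


def extract_dwells(path: StatePath) -> list[DwellRecord]:
    """Direction-resolved dwell records for every interior sojourn.

    Paths with fewer than 3 sojourns contain no interior sojourn and yield an
    empty list.
    """
    if len(path) < 3:
        logger.info("path with %d sojourn(s): no interior dwells", len(path))
        return []
    return [
        DwellRecord(path.states[i], float(path.durations[i]), path.states[i + 1])
        for i in range(1, len(path) - 1)
    ]


def fit_exponential(
    durations: Sequence[float],
    floor: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    dead_time: float = 0.0,
    lsq_fit: bool = True,
) -> ExponentialFit:
    """Fit a single-exponential lifetime to a set of dwell durations (ms).

    The primary estimate is the MLE (sample mean); the confidence interval is
    a 95% bootstrap percentile interval.  ``dead_time`` optionally applies a
    first-order missed-event correction by adding the detection dead time to
    the estimate.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < floor:
        raise InsufficientDwellsError(d.size, floor)
    if np.any(d <= 0):
        raise ParameterError("durations must be positive")
    tau = float(d.mean()) + dead_time
    rng = np.random.default_rng(seed)
    boot = d[rng.integers(0, d.size, size=(n_boot, d.size))].mean(axis=1) + dead_time
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    tau_lsq = None
    if lsq_fit:
        tau_lsq = _histogram_lifetime(d)
        if tau_lsq is not None:
            tau_lsq += dead_time
    return ExponentialFit(tau=tau, ci=ci, n=int(d.size), tau_lsq=tau_lsq)


def _histogram_lifetime(d: np.ndarray) -> float | None:
    """Least-squares A*exp(-t/tau) fit to a Freedman-Diaconis dwell histogram."""
    try:
        counts, edges = np.histogram(d, bins="fd")
    except MemoryError:  # pragma: no cover - pathological spread
        return None
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        return None
    try:
        popt, _ = curve_fit(
            lambda t, A, tau: A * np.exp(-t / tau),
            centers[mask],
            counts[mask],
            p0=(counts.max(), d.mean()),
            maxfev=10_000,
        )
        return float(popt[1])
    except RuntimeError:
        return None


@dataclass
class KineticMatrix:
    """Estimated transition probabilities and direction-resolved lifetimes.

    ``P_hat[i][j]`` is the fraction of exits from ``i`` landing in ``j``;
    ``counts[i][j]`` the underlying exit counts; ``tau_hat[i][j]`` the fitted
    mean lifetime of ``i`` sojourns ending in ``j`` (None where the count is
    below the fit floor).
    """

    states: tuple[str, ...]
    counts: dict[str, dict[str, int]]
    P_hat: dict[str, dict[str, float]]
    tau_hat: dict[str, dict[str, ExponentialFit | None]]

    def exit_count(self, state: str) -> int:
        return sum(self.counts.get(state, {}).values())

    def low_state_lifetime(self) -> float:
        """Destination-averaged mean lifetime of the low (duplex) state, ms."""
        row_p = self.P_hat.get("low", {})
        row_t = self.tau_hat.get("low", {})
        num = den = 0.0
        for j, p in row_p.items():
            f = row_t.get(j)
            if f is not None:
                num += p * f.tau
                den += p
        if den == 0:
            raise ParameterError("no low-state lifetime estimates available")
        return num / den

    def unwinding_probability(self) -> float:
        """P_hat(low -> high): duplex unwinding straight to the single strand."""
        return self.P_hat.get("low", {}).get("high", 0.0)

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "counts": self.counts,
            "P_hat": self.P_hat,
            "tau_hat": {
                i: {
                    j: None
                    if f is None
                    else {"tau_ms": f.tau, "ci": list(f.ci), "n": f.n, "tau_lsq_ms": f.tau_lsq}
                    for j, f in row.items()
                }
                for i, row in self.tau_hat.items()
            },
        }


def kinetic_summary(
    dwells: Sequence[DwellRecord],
    floor: int = 10,
    seed: int = 0,
    dead_time: float = 0.0,
) -> KineticMatrix:
    """Assemble the transition-probability / mean-lifetime matrix from dwells."""
    if not dwells:
        raise ParameterError("no dwell records")
    by_dir: dict[tuple[str, str], list[float]] = {}
    for r in dwells:
        by_dir.setdefault((r.state, r.next_state), []).append(r.duration)

    seen = {k[0] for k in by_dir} | {k[1] for k in by_dir}
    observed = [s for s in STATES if s in seen] + sorted(seen - set(STATES))
    counts: dict[str, dict[str, int]] = {}
    P_hat: dict[str, dict[str, float]] = {}
    tau_hat: dict[str, dict[str, ExponentialFit | None]] = {}
    for i in observed:
        row = {j: by_dir.get((i, j), []) for j in observed if j != i and (i, j) in by_dir}
        if not row:
            continue
        total = sum(len(v) for v in row.values())
        counts[i] = {j: len(v) for j, v in row.items()}
        P_hat[i] = {j: len(v) / total for j, v in row.items()}
        tau_hat[i] = {}
        for j, v in row.items():
            try:
                tau_hat[i][j] = fit_exponential(v, floor=floor, seed=seed, dead_time=dead_time)
            except InsufficientDwellsError:
                logger.warning("direction %s->%s has only %d dwells; no lifetime fit", i, j, len(v))
                tau_hat[i][j] = None
    return KineticMatrix(states=tuple(observed), counts=counts, P_hat=P_hat, tau_hat=tau_hat)


@dataclass
class OccupancyTable:
    """Time-weighted percentage of the recording spent in each state."""

    percent: dict[str, float]
    total_time: float  # ms

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 0.01:
            raise ParameterError(f"occupancies must sum to 100, got {total}")

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {s: round(p, ndigits) for s, p in self.percent.items()}

    def as_vector(self, states: Sequence[str] = STATES) -> np.ndarray:
        return np.array([self.percent.get(s, 0.0) for s in states])


def occupancy(path: StatePath) -> OccupancyTable:
    """Whole-path time fraction per state (no censoring)."""
    if len(path) == 0:
        raise ParameterError("empty path")
    total = path.total_duration
    if total <= 0:
        raise ParameterError("path has zero total duration")
    acc: dict[str, float] = {}
    for s, d in path:
        acc[s] = acc.get(s, 0.0) + d
    ordered = [s for s in STATES if s in acc] + [s for s in acc if s not in STATES]
    return OccupancyTable(
        percent={s: 100.0 * acc[s] / total for s in ordered},
        total_time=total,
    )
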
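"""Trace idealization: amplitude-histogram mixture fitting and HMM decoding.

This is the stage that turns a noisy current recording into a discrete
sequence of conformational sojourns.  It proceeds in two steps:

1. :func:`fit_amplitude_histogram` fits Gaussian mixtures with 1..k_max
   components to the raw current samples and selects the component count by
   BIC.  The selected ``k`` doubles as the level count used to classify
   recordings (3 = target-bound three-state dynamics, 2 = hairpin
   folding/unfolding control, 1 = blank device).
2. :func:`idealize_trace` runs a Gaussian-emission hidden Markov model with
   the fitted emission parameters, estimates the transition matrix by EM from
   a near-diagonal start, Viterbi-decodes the most likely state sequence, and
   merges it into dwells.

Baseline convention: the folded-hairpin conductance is the "0" reference.
For a three-component fit the middle component is the baseline (the hairpin,
flanked by the duplex below and the single strand above); for a two-component
fit the lower component is the baseline (the folded hairpin of the
target-free control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.mixture import GaussianMixture

from .models import ParameterError, StatePath, Trace, path_from_samples


class InsufficientDataError(ValueError):
    """Raised when a trace is too short for a meaningful fit."""


class NoDynamicsError(ValueError):
    """Raised when idealization is requested for a single-level (blank) fit."""


#: State labels per selected component count, sorted by conductance level.
LABELS_BY_K = {
    1: ("intermediate",),
    2: ("intermediate", "high"),
    3: ("low", "intermediate", "high"),
}

#: Index of the baseline ("0") component among level-sorted components.
BASELINE_INDEX_BY_K = {1: 0, 2: 0, 3: 1}


@dataclass
class MixtureFit:
    """Result of amplitude-histogram mixture fitting.

    ``means`` are reported relative to the baseline component (which is
    therefore exactly 0); ``offset`` is the baseline's absolute current so the
    original scale can be recovered.  Components are sorted by level.
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic_scores: dict[int, float]
    baseline_index: int
    offset: float = 0.0
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = LABELS_BY_K[self.k]


def fit_amplitude_histogram(
    trace: Trace,
    k_max: int = 3,
    max_samples: int = 100_000,
) -> MixtureFit:
    """Fit Gaussian mixtures with 1..k_max components; select k by minimum BIC.

    Fitting operates on the raw samples (no binning).  Traces longer than
    ``max_samples`` are subsampled with an even stride for speed; the mixture
    likelihood is insensitive to this for stationary traces.
    """
    if k_max not in (1, 2, 3):
        raise ParameterError("k_max must be 1, 2, or 3")
    x = trace.values
    if x.size < 100:
        raise InsufficientDataError(f"need >= 100 samples, got {x.size}")
    if x.size > max_samples:
        x = x[:: int(np.ceil(x.size / max_samples))]
    X = x.reshape(-1, 1)

    bic: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        # quantile means + common sd start, multiple EM restarts, fixed seed
        q = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            means_init=q,
            n_init=1,
            random_state=0,
            max_iter=300,
        )
        try:
            gm.fit(X)
            if k > 1:
                best = gm
                for restart in range(9):
                    alt = GaussianMixture(
                        n_components=k,
                        covariance_type="spherical",
                        n_init=1,
                        random_state=restart + 1,
                        max_iter=300,
                    ).fit(X)
                    if alt.lower_bound_ > best.lower_bound_:
                        best = alt
                gm = best
            if not gm.converged_:
                warnings.warn(f"mixture EM did not converge for k={k}; excluded", stacklevel=2)
                continue
            fits[k] = gm
            bic[k] = float(gm.bic(X))
        except Exception as exc:  # noqa: BLE001 - per-k failure is non-fatal
            warnings.warn(f"mixture fit failed for k={k}: {exc}", stacklevel=2)
    if not fits:
        raise ParameterError("mixture fitting failed for every candidate k")

    k_best = min(bic, key=bic.get)
    gm = fits[k_best]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    b = BASELINE_INDEX_BY_K[k_best]
    offset = float(means[b])
    return MixtureFit(
        k=k_best,
        means=means - offset,
        sds=sds,
        weights=weights,
        bic_scores=bic,
        baseline_index=b,
        offset=offset,
    )


def idealize_trace(
    trace: Trace,
    fit: MixtureFit,
    min_dwell_samples: int = 2,
    em_iterations: int = 20,
) -> StatePath:
    """Decode the most likely state sequence and merge it into dwells.

    A Gaussian-emission HMM with ``fit.k`` states is used: emission means and
    sds are fixed from the mixture fit, the transition matrix is re-estimated
    by EM starting near-diagonal (sticky states), and the path is decoded with
    the Viterbi algorithm.  Dwells shorter than ``min_dwell_samples`` are
    merged into the longer neighbouring dwell (ties go to the preceding one) —
    sub-filter-rise-time blips are detection artifacts, not sojourns.
    """
    if fit.k < 2:
        raise NoDynamicsError("single-level fit: no dynamics to idealize (blank device)")
    X = trace.values.reshape(-1, 1)
    k = fit.k
    hmm = GaussianHMM(
        n_components=k,
        covariance_type="diag",
        init_params="",
        params="st",  # emissions stay fixed at the mixture estimates
        n_iter=em_iterations,
        random_state=0,
    )
    hmm.startprob_ = np.full(k, 1.0 / k)
    stick = 0.98
    hmm.transmat_ = np.full((k, k), (1.0 - stick) / (k - 1)) + np.eye(k) * (
        stick - (1.0 - stick) / (k - 1)
    )
    hmm.means_ = (fit.means + fit.offset).reshape(-1, 1)
    hmm.covars_ = np.maximum(fit.sds, 1e-6).reshape(-1, 1) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(X)
    decoded = hmm.predict(X)

    # components are level-sorted already (means from MixtureFit are sorted)
    labels = [fit.labels[s] for s in decoded]
    path = path_from_samples(labels, trace.dt)
    return _merge_short_dwells(path, min_dwell_samples * trace.dt)


def _merge_short_dwells(path: StatePath, min_duration: float) -> StatePath:
    """Absorb dwells shorter than ``min_duration`` into the longer neighbour."""
    states = list(path.states)
    durations = list(path.durations)
    changed = True
    while changed and len(states) > 1:
        changed = False
        # resolve the shortest offending dwell first for determinism
        idx = None
        shortest = min_duration
        for i, d in enumerate(durations):
            if d < shortest:
                shortest = d
                idx = i
        if idx is None:
            break
        prev_d = durations[idx - 1] if idx > 0 else -1.0
        next_d = durations[idx + 1] if idx < len(states) - 1 else -1.0
        target = idx - 1 if prev_d >= next_d else idx + 1
        merged = durations.pop(idx)
        states.pop(idx)
        if target > idx:
            target -= 1
        durations[target] += merged
        # merging may create adjacent equal states; collapse them
        j = 1
        while j < len(states):
            if states[j] == states[j - 1]:
                durations[j - 1] += durations.pop(j)
                states.pop(j)
            else:
                j += 1
        changed = True
    return StatePath(states=states, durations=np.asarray(durations))
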
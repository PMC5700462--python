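"""Synthetic trace, state-path, control-recording, and melting-curve generation.

Every generator takes an explicit integer seed and owns no global state, so
any downstream analysis can be exercised reproducibly without instrument data.

The trace generator emulates the recording chain of a hairpin-DNA-decorated
SiNW FET: a piecewise-constant conformational level signal at three (target
present), two (hairpin folding/unfolding control) or one (blank device) level,
additive Gaussian measurement noise band-limited by the acquisition low-pass
filter, and an optional 1/f background.  Default sampling is 28.8 kSa/s after
a 5 kHz low-pass filter.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .models import STATES, KineticModel, MeltingCurve, ParameterError, StatePath, Trace


def simulate_state_path(
    model: KineticModel,
    n_exits: int,
    seed: int,
    initial_state: str | None = None,
) -> StatePath:
    """Sample a semi-Markov conformational path with ``n_exits`` completed sojourns.

    From state ``i`` the destination ``j`` is drawn first with probability
    ``P[i][j]``, then the sojourn duration from an exponential with mean
    ``tau[i][j]`` (ms).  Drawing the destination first is what lets the mean
    dwell of a state depend on the conformation that follows it.

    Parameters
    ----------
    model
        Generative parameters (validated).
    n_exits
        Number of completed sojourns to generate (>= 1).
    seed
        Seed for the path's private random generator.
    initial_state
        Starting state label; default "intermediate" if present (the folded
        hairpin, the resting conformation), else the first state.
    """
    model.validate()
    if n_exits < 1:
        raise ParameterError("n_exits must be >= 1")
    rng = np.random.default_rng(seed)
    if initial_state is None:
        initial_state = "intermediate" if "intermediate" in model.states else model.states[0]
    i = model.state_index(initial_state)

    n = model.n_states
    # Per-state destination samplers: inverse-CDF on the exit distribution.
    cdfs = np.cumsum(model.P, axis=1)
    states_idx = np.empty(n_exits, dtype=np.intp)
    durations = np.empty(n_exits)
    u_dest = rng.random(n_exits)
    u_dur = rng.random(n_exits)
    for k in range(n_exits):
        j = int(np.searchsorted(cdfs[i], u_dest[k], side="right"))
        j = min(j, n - 1)
        # Exponential via inverse CDF so one uniform stream drives everything.
        durations[k] = -model.tau[i, j] * np.log1p(-u_dur[k])
        states_idx[k] = i
        i = j
    return StatePath(states=[model.states[s] for s in states_idx], durations=durations)


def stationary_occupancy(model: KineticModel) -> dict[str, float]:
    """Long-run time fraction per state, closed form.

    The embedded jump chain's stationary distribution ``pi`` (solving
    ``pi P = pi``) is weighted by the destination-averaged mean sojourn
    ``d_i = sum_j P[i][j] tau[i][j]``; time fractions are
    ``pi_i d_i / sum_k pi_k d_k``.
    """
    model.validate()
    n = model.n_states
    A = np.vstack([model.P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    w = pi * model.mean_dwell()
    w /= w.sum()
    return dict(zip(model.states, w))


def _pink_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f noise with the requested RMS, synthesized spectrally."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC offset
    pink = np.fft.irfft(spec * scale, n)
    sd = pink.std()
    return pink * (rms / sd) if sd > 0 else pink


def render_trace(path: StatePath, model: KineticModel, seed: int) -> Trace:
    """Render a StatePath into a sampled current trace.

    The conformational signal is piecewise constant at the model levels; on
    top of it Gaussian noise (sd ``noise_sd``) plus an optional 1/f component
    are added after band-limiting the noise with a single-pole low-pass at
    ``filter_cutoff``.  The filter acts on the noise process only: the level
    transitions themselves are fast compared with the filter rise time, so the
    rendered step edges stay sharp and a noiseless trace is exactly the level
    sequence.

    Dwells shorter than one sampling interval are kept for one sample (with a
    warning); at 28.8 kSa/s and millisecond-scale lifetimes this is rare.
    """
    model.validate()
    if len(path) == 0:
        raise ParameterError("cannot render an empty path")
    dt = 1.0 / model.sample_rate  # ms per sample
    edges = np.concatenate([[0.0], np.cumsum(path.durations)])
    counts = np.diff(np.round(edges / dt).astype(np.int64))
    short = counts < 1
    if np.any(short):
        warnings.warn(
            f"{int(short.sum())} dwell(s) shorter than one sample were clamped "
            "to one sample",
            stacklevel=2,
        )
        counts[short] = 1
    level_of = dict(zip(model.states, model.levels))
    try:
        state_levels = np.array([level_of[s] for s in path.states])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ParameterError(f"path state {exc} not in model") from exc
    values = np.repeat(state_levels, counts)

    n = values.size
    rng = np.random.default_rng(seed)
    noise = np.zeros(n)
    if model.noise_sd > 0:
        noise += rng.normal(0.0, model.noise_sd, n)
    if model.pink_amplitude > 0:
        noise += _pink_noise(n, model.pink_amplitude, rng)
    if noise.any() and model.filter_cutoff > 0:
        nyquist = model.sample_rate / 2.0  # kHz
        if model.filter_cutoff < nyquist:
            b, a = signal.butter(1, model.filter_cutoff / nyquist)
            # renormalize so the filtered noise keeps its nominal sd
            raw_sd = noise.std()
            noise = signal.lfilter(b, a, noise)
            if noise.std() > 0:
                noise *= raw_sd / noise.std()
    return Trace(dt=dt, values=values + noise, metadata={"temperature_C": 45.0, "bias_mV": 200.0})


def two_level_model(
    tau_folded: float = 10.0,
    tau_unfolded: float = 2.0,
    level_unfolded: float = 3.0,
    noise_sd: float = 0.5,
    pink_amplitude: float = 0.0,
    sample_rate: float = 28.8,
    filter_cutoff: float = 5.0,
) -> KineticModel:
    """Two-state hairpin folding/unfolding model (target-free control).

    The folded hairpin is the conductance baseline (0 nA, "intermediate");
    the unfolded coil sits at ``level_unfolded`` ("high").  Dwell means are
    package defaults, chosen at the millisecond scale of the three-state
    kinetics.
    """
    return KineticModel(
        states=("intermediate", "high"),
        levels=np.array([0.0, level_unfolded]),
        P=np.array([[0.0, 1.0], [1.0, 0.0]]),
        tau=np.array([[0.0, tau_folded], [tau_unfolded, 0.0]]),
        noise_sd=noise_sd,
        pink_amplitude=pink_amplitude,
        sample_rate=sample_rate,
        filter_cutoff=filter_cutoff,
    )


def simulate_control_trace(kind: str, seed: int, duration_ms: float = 500.0, **params) -> Trace:
    """Simulate a control recording.

    ``kind="two_level"``: hairpin folding/unfolding in pure buffer (two
    Gaussian conductance peaks).  ``kind="blank"``: a device without a
    tethered probe — a flat zero-level trace carrying only Gaussian plus 1/f
    noise (single conductance peak).  Extra keyword arguments are forwarded
    to :func:`two_level_model` or (for blank) override ``noise_sd``,
    ``pink_amplitude``, ``sample_rate``, ``filter_cutoff``.
    """
    if kind == "two_level":
        model = two_level_model(**params)
        mean_sojourn = model.mean_dwell().mean()
        n_exits = max(2, int(np.ceil(duration_ms / mean_sojourn)))
        path = simulate_state_path(model, n_exits, seed=seed)
        return render_trace(path, model, seed=seed + 1)
    if kind == "blank":
        noise_sd = params.get("noise_sd", 0.2)
        pink_amplitude = params.get("pink_amplitude", 0.3)
        sample_rate = params.get("sample_rate", 28.8)
        filter_cutoff = params.get("filter_cutoff", 5.0)
        n = max(2, int(np.ceil(duration_ms * sample_rate)))
        rng = np.random.default_rng(seed)
        noise = np.zeros(n)
        if noise_sd > 0:
            noise += rng.normal(0.0, noise_sd, n)
        if pink_amplitude > 0:
            noise += _pink_noise(n, pink_amplitude, rng)
        if noise.any() and 0 < filter_cutoff < sample_rate / 2:
            b, a = signal.butter(1, filter_cutoff / (sample_rate / 2))
            raw_sd = noise.std()
            noise = signal.lfilter(b, a, noise)
            if noise.std() > 0:
                noise *= raw_sd / noise.std()
        return Trace(dt=1.0 / sample_rate, values=noise, metadata={"kind": "blank"})
    raise ParameterError(f"unknown control kind {kind!r}; expected 'two_level' or 'blank'")


def simulate_melting_curve(
    t_m: float,
    slope: float,
    temps,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltingCurve:
    """Two-state melting curve: normalized unfolded fraction vs temperature.

    ``f(T) = 1 / (1 + exp((t_m - T) / slope))`` with additive Gaussian noise
    of sd ``noise_sd`` on the normalized absorbance.
    """
    if slope <= 0:
        raise ParameterError("slope must be positive")
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0 or np.any(np.diff(temps) <= 0):
        raise ParameterError("temperatures must be nonempty and strictly ascending")
    frac = 1.0 / (1.0 + np.exp((t_m - temps) / slope))
    if noise_sd > 0:
        frac = frac + np.random.default_rng(seed).normal(0.0, noise_sd, temps.size)
    return MeltingCurve(temperatures=temps, absorbance=frac)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate_hairpin_stem(sequence: str, stem_len: int) -> bool:
    """Check that a probe sequence can fold into a hairpin with the given stem.

    True iff the first ``stem_len`` bases are the reverse complement of the
    last ``stem_len`` bases, so the two ends can hybridize into a duplex stem.
    Any 5' amine/carbon linker is metadata, not sequence.
    """
    if stem_len <= 0:
        raise ParameterError("stem_len must be positive")
    sequence = sequence.upper()
    if set(sequence) - set("ACGT"):
        raise ParameterError("sequence must contain only A, C, G, T")
    if 2 * stem_len > len(sequence):
        raise ParameterError("sequence shorter than two stems")
    head = sequence[:stem_len]
    tail = sequence[-stem_len:]
    return head == tail.translate(_COMPLEMENT)[::-1]
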
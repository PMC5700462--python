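"""Core domain types for three-state single-molecule FET trace analysis.

The physical picture: a single hairpin-DNA probe tethered to a silicon-nanowire
field-effect transistor produces a fluctuating source-drain current whose level
tracks the probe conformation.  In the presence of a target strand three
conductance levels are resolved and are assigned, from lowest to highest, to
the probe-target duplex ("low"), the folded hairpin ("intermediate", the
conductance baseline), and the unfolded single strand ("high").

Kinetics are modelled as a semi-Markov jump process: from state ``i`` the
destination ``j`` is drawn with exit probability ``P[i][j]`` and the sojourn
duration from an exponential with a destination-resolved mean ``tau[i][j]``.
Destination-resolved means are required because the measured lifetime of a
state differs depending on which conformation follows it, which a memoryless
continuous-time Markov chain cannot produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

#: Canonical conformational state labels, ordered by conductance level.
STATES = ("low", "intermediate", "high")


class ParameterError(ValueError):
    """Raised when a model, path, trace, or curve violates its invariants."""


@dataclass
class KineticModel:
    """Generative parameters of the three-level (or two-level) trace model.

    Parameters
    ----------
    states
        Ordered state labels, lowest conductance first.
    levels
        Mean current per state in nA, strictly increasing with state order.
    P
        Destination-resolved exit probabilities; square, zero diagonal, each
        row summing to 1 over the other states.
    tau
        Destination-resolved mean dwell times in ms; positive wherever the
        corresponding ``P`` entry is nonzero.
    noise_sd
        Standard deviation of the additive Gaussian measurement noise, nA.
    pink_amplitude
        RMS amplitude of an optional 1/f background component, nA (0 disables).
    sample_rate
        Sampling rate in kSa/s (samples per ms).
    filter_cutoff
        Low-pass bandwidth of the recording chain in kHz.
    """

    states: tuple[str, ...] = STATES
    levels: np.ndarray = field(default_factory=lambda: np.array([-3.0, 0.0, 3.0]))
    P: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    tau: np.ndarray = field(default_factory=lambda: np.ones((3, 3)))
    noise_sd: float = 0.5
    pink_amplitude: float = 0.0
    sample_rate: float = 28.8
    filter_cutoff: float = 5.0

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.levels = np.asarray(self.levels, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.states)

    def validate(self) -> None:
        n = self.n_states
        if n < 2:
            raise ParameterError("a kinetic model needs at least two states")
        if self.levels.shape != (n,) or self.P.shape != (n, n) or self.tau.shape != (n, n):
            raise ParameterError("levels/P/tau shapes inconsistent with the state list")
        if np.any(np.diff(self.levels) <= 0):
            raise ParameterError("state levels must be strictly increasing")
        if np.any(np.diag(self.P) != 0):
            raise ParameterError("self-transitions are not allowed (P[i][i] must be 0)")
        if np.any(self.P < 0) or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-8):
            raise ParameterError("each row of P must be a probability vector over j != i")
        if np.any(self.tau[self.P > 0] <= 0):
            raise ParameterError("tau[i][j] must be > 0 wherever P[i][j] > 0")
        if self.sample_rate <= 0 or self.noise_sd < 0 or self.pink_amplitude < 0:
            raise ParameterError("sample_rate must be > 0; noise amplitudes must be >= 0")

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    def mean_dwell(self) -> np.ndarray:
        """Destination-averaged mean sojourn per state, ms: sum_j P[i][j] tau[i][j]."""
        return (self.P * self.tau).sum(axis=1)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "levels": self.levels.tolist(),
            "P": self.P.tolist(),
            "tau": self.tau.tolist(),
            "noise_sd": self.noise_sd,
            "pink_amplitude": self.pink_amplitude,
            "sample_rate": self.sample_rate,
            "filter_cutoff": self.filter_cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(
            states=tuple(d.get("states", STATES)),
            levels=np.asarray(d["levels"], dtype=float),
            P=np.asarray(d["P"], dtype=float),
            tau=np.asarray(d["tau"], dtype=float),
            noise_sd=float(d.get("noise_sd", 0.5)),
            pink_amplitude=float(d.get("pink_amplitude", 0.0)),
            sample_rate=float(d.get("sample_rate", 28.8)),
            filter_cutoff=float(d.get("filter_cutoff", 5.0)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "KineticModel":
        path = Path(path)
        d = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(d)


@dataclass
class StatePath:
    """An idealized trace: ordered (state label, dwell duration in ms) pairs."""

    states: list[str]
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.states = list(self.states)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.states) != len(self.durations):
            raise ParameterError("states and durations differ in length")
        if len(self.states) and np.any(self.durations <= 0):
            raise ParameterError("dwell durations must be positive")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ParameterError("consecutive sojourns must differ in state")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(zip(self.states, self.durations))

    @property
    def total_duration(self) -> float:
        """Total path duration, ms."""
        return float(self.durations.sum())


@dataclass
class Trace:
    """A uniformly sampled current recording.

    ``dt`` is the sampling interval in ms; ``values`` the current in nA.
    ``metadata`` carries annotations only (temperature in deg C, bias in mV).
    """

    dt: float
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ParameterError("sampling interval dt must be positive")
        if self.values.size < 2:
            raise ParameterError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")

    @property
    def sample_rate(self) -> float:
        """Sampling rate, kSa/s."""
        return 1.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times, ms."""
        return np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


@dataclass
class MeltingCurve:
    """Normalized A260 absorbance versus temperature."""

    temperatures: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.temperatures.shape != self.absorbance.shape:
            raise ParameterError("temperature and absorbance arrays differ in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ParameterError("temperatures must be strictly increasing")


def path_from_samples(labels: Sequence[str], dt: float) -> StatePath:
    """Collapse a per-sample label sequence into a StatePath (durations in ms)."""
    labels = list(labels)
    if not labels:
        raise ParameterError("empty label sequence")
    arr = np.asarray(labels, dtype=object)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return StatePath(
        states=[labels[s] for s in starts],
        durations=(ends - starts) * dt,
    )
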
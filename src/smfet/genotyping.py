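"""Allele discrimination from multi-device occupancy profiles and kinetics.

The discriminating observable is the time fraction spent in the low
(probe-target duplex) conductance state: a well-matched target stabilizes the
duplex and dominates the low state, while single-base mismatched targets
leave the probe mostly in the hairpin conformation.  Occupancies from
replicate devices are aggregated as mean +/- sample standard deviation, and
an observed profile is called against reference profiles by a standardized
Euclidean distance on the three state percentages.

Two kinetic orderings back the occupancy call: the destination-averaged mean
lifetime of the low state (duplex stability, descending with mismatch
severity) and the probability that a duplex sojourn exits straight to the
single strand (unwinding, ascending with mismatch severity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .kinetics import KineticMatrix, OccupancyTable
from .models import STATES, KineticModel, ParameterError


@dataclass
class AggregateOccupancy:
    """Per-state mean and dispersion of occupancy percentages across devices."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_devices: int

    def __post_init__(self) -> None:
        total = sum(self.mean.values())
        if abs(total - 100.0) > 0.2:
            raise ParameterError(f"mean occupancies must sum to ~100, got {total}")
        if self.n_devices < 1:
            raise ParameterError("need at least one device")

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {s: round(m, ndigits) for s, m in self.mean.items()}

    def as_vector(self, states: Sequence[str] = STATES) -> np.ndarray:
        return np.array([self.mean.get(s, 0.0) for s in states])

    def sd_vector(self, states: Sequence[str] = STATES) -> np.ndarray:
        return np.array([self.sd.get(s, 0.0) for s in states])


@dataclass
class AlleleCall:
    """Result of matching an occupancy profile against reference alleles."""

    label: str
    low_percent: float
    distances: dict[str, float]
    tie: bool
    ordering: list[str]  # reference labels sorted by distance, closest first

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "low_percent": self.low_percent,
            "distances": self.distances,
            "tie": self.tie,
            "ordering": self.ordering,
        }


def aggregate_occupancy(tables: Sequence[OccupancyTable]) -> AggregateOccupancy:
    """Arithmetic mean and sample standard deviation per state across devices."""
    if not tables:
        raise ParameterError("no occupancy tables to aggregate")
    state_sets = [tuple(t.percent) for t in tables]
    if len(set(state_sets)) > 1:
        raise ParameterError(f"mismatched state sets across tables: {sorted(set(state_sets))}")
    states = state_sets[0]
    mat = np.array([[t.percent[s] for s in states] for t in tables])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(tables) > 1 else np.zeros(len(states))
    return AggregateOccupancy(
        mean=dict(zip(states, mean)),
        sd=dict(zip(states, sd)),
        n_devices=len(tables),
    )


def aggregate_percentages(device_percent: Sequence[Sequence[float]],
                          states: Sequence[str] = STATES) -> AggregateOccupancy:
    """Aggregate raw per-device percentage rows (convenience for tabulated data)."""
    mat = np.asarray(device_percent, dtype=float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    return AggregateOccupancy(
        mean=dict(zip(states, mean)), sd=dict(zip(states, sd)), n_devices=mat.shape[0]
    )


def call_allele(
    observed: AggregateOccupancy,
    references: Mapping[str, AggregateOccupancy],
    dispersion_floor: float = 0.5,
) -> AlleleCall:
    """Nearest-reference allele call on the 3-vector of state percentages.

    Distance is Euclidean after standardizing each coordinate by the
    reference profile's dispersion, floored at ``dispersion_floor`` percentage
    points so that near-zero dispersions do not dominate.  Exact distance ties
    are broken toward the profile with the larger low-state percentage and
    flagged.
    """
    if not references:
        raise ParameterError("reference map is empty")
    states = tuple(observed.mean)
    obs = observed.as_vector(states)
    distances: dict[str, float] = {}
    for label, ref in references.items():
        scale = np.maximum(ref.sd_vector(states), dispersion_floor)
        distances[label] = float(np.linalg.norm((obs - ref.as_vector(states)) / scale))
    d_min = min(distances.values())
    winners = [l for l, d in distances.items() if d == d_min]
    tie = len(winners) > 1
    if tie:
        winners.sort(key=lambda l: -references[l].mean.get("low", 0.0))
    ordering = sorted(distances, key=lambda l: (distances[l], -references[l].mean.get("low", 0.0)))
    return AlleleCall(
        label=winners[0],
        low_percent=observed.mean.get("low", 0.0),
        distances=distances,
        tie=tie,
        ordering=ordering,
    )


@dataclass
class StabilityReport:
    """Allele rankings by duplex stability and by unwinding probability."""

    lifetime_order: list[str]  # descending destination-averaged low-state lifetime
    unwinding_order: list[str]  # descending P_hat(low -> high)
    lifetimes: dict[str, float]
    unwinding: dict[str, float]
    lifetime_ties: list[tuple[str, str]]
    unwinding_ties: list[tuple[str, str]]


def rank_stability(matrices: Mapping[str, KineticMatrix]) -> StabilityReport:
    """Rank alleles by low-state lifetime and by unwinding probability."""
    lifetimes: dict[str, float] = {}
    unwinding: dict[str, float] = {}
    for label, m in matrices.items():
        try:
            lifetimes[label] = m.low_state_lifetime()
        except ParameterError:
            import warnings

            warnings.warn(f"{label}: no low-state lifetime estimates; excluded", stacklevel=2)
            continue
        unwinding[label] = m.unwinding_probability()

    def ties(d: dict[str, float]) -> list[tuple[str, str]]:
        labels = sorted(d)
        return [
            (a, b)
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
            if d[a] == d[b]
        ]

    return StabilityReport(
        lifetime_order=sorted(lifetimes, key=lifetimes.get, reverse=True),
        unwinding_order=sorted(unwinding, key=unwinding.get, reverse=True),
        lifetimes=lifetimes,
        unwinding=unwinding,
        lifetime_ties=ties(lifetimes),
        unwinding_ties=ties(unwinding),
    )


# -- bundled reference profiles -------------------------------------------


def _reference_data() -> dict:
    with resources.files("smfet.data").joinpath("reference_profiles.json").open() as fh:
        return json.load(fh)


def load_reference_occupancies(per_device: bool = False):
    """Reference occupancy profiles for the four target alleles.

    With ``per_device=True`` returns the raw device percentage rows instead of
    the aggregated profiles.
    """
    data = _reference_data()
    states = tuple(data["states"])
    if per_device:
        return {
            label: np.asarray(entry["device_percent"], dtype=float)
            for label, entry in data["occupancy"].items()
        }
    out: dict[str, AggregateOccupancy] = {}
    for label, entry in data["occupancy"].items():
        out[label] = AggregateOccupancy(
            mean=dict(zip(states, entry["avg_percent"])),
            sd=dict(zip(states, entry["avg_pm"])),
            n_devices=len(entry["device_percent"]),
        )
    return out


def load_reference_models(
    noise_sd: float = 0.5,
    pink_amplitude: float = 0.0,
    device: int = 0,
) -> dict[str, KineticModel]:
    """Generative kinetic models for the four alleles.

    Transition probabilities and destination-resolved lifetimes come from the
    reference kinetic matrices; current levels from the chosen reference
    device (0-based index into the five recordings per allele).
    """
    data = _reference_data()
    out: dict[str, KineticModel] = {}
    for label, entry in data["kinetics"].items():
        levels = data["occupancy"][label]["device_levels_nA"][device]
        out[label] = KineticModel(
            states=tuple(data["states"]),
            levels=np.asarray(levels, dtype=float),
            P=np.asarray(entry["P"], dtype=float),
            tau=np.where(np.asarray(entry["P"]) > 0, np.asarray(entry["tau_ms"]), 1.0),
            noise_sd=noise_sd,
            pink_amplitude=pink_amplitude,
            sample_rate=data["sample_rate_kSa_s"],
            filter_cutoff=data["filter_cutoff_kHz"],
        )
    return out


def reference_melting() -> dict:
    """Reference melting temperatures (hairpin, well-matched duplex, ordering)."""
    return _reference_data()["melting"]


def reference_sequence() -> tuple[str, int]:
    """The hairpin probe sequence and its stem length."""
    data = _reference_data()
    return data["hairpin_sequence"], int(data["stem_length"])
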
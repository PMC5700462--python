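"""End-to-end orchestration: simulate or load traces, idealize, summarize,
aggregate across replicates, and call alleles.

:func:`run_pipeline` is the programmatic entry point; the command-line
interface in :mod:`smfet.cli` is a thin wrapper around it.  Given identical
configuration and seeds the report bundle is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import genotyping, idealization, io, kinetics, synthetic
from .models import KineticModel, ParameterError, StatePath

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``mode="simulate"`` generates one trace per allele/replicate from kinetic
    model files (or the bundled reference models when ``alleles`` maps to
    None); ``mode="load"`` reads trace files from disk.
    """

    mode: str = "simulate"  # "simulate" | "load"
    alleles: dict[str, str | None] = field(default_factory=dict)  # label -> model/trace path
    n_exits: int = 2000
    n_replicates: int = 1
    seed: int = 0
    idealize_from_trace: bool = False  # simulate mode: render+idealize vs direct path
    k_max: int = 3
    min_dwell_samples: int = 2
    fit_floor: int = 10
    out_dir: str = "smfet_out"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if not isinstance(self.seed, int):
            raise ParameterError("seed must be an integer")
        if self.mode == "load":
            for label, p in self.alleles.items():
                if p is None or not Path(p).exists():
                    raise ParameterError(f"trace path for {label!r} missing: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _allele_seed(base: int, idx: int, rep: int) -> int:
    return (base + 7919 * idx + 104729 * rep) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain and write a report bundle to ``out_dir``.

    Returns the in-memory report: per-allele occupancy tables, kinetic
    matrices, the aggregate occupancies, the stability rankings, and the
    allele call of each observed profile against the bundled references.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate":
        models = genotyping.load_reference_models()
        labels = list(config.alleles) or list(models)
    else:
        labels = list(config.alleles)

    per_allele: dict[str, dict] = {}
    for idx, label in enumerate(labels):
        occ_tables = []
        matrix = None
        all_dwells: list[kinetics.DwellRecord] = []
        for rep in range(config.n_replicates):
            seed = _allele_seed(config.seed, idx, rep)
            path = _obtain_path(config, label, models if config.mode == "simulate" else None, seed)
            occ = kinetics.occupancy(path)
            occ_tables.append(occ)
            all_dwells.extend(kinetics.extract_dwells(path))
            io.write_state_path(path, out / f"{_slug(label)}_rep{rep}_path.tsv")
        io.write_json(
            [io.occupancy_report(t) for t in occ_tables], out / f"{_slug(label)}_occupancy.json"
        )
        if all_dwells:
            matrix = kinetics.kinetic_summary(
                all_dwells, floor=config.fit_floor, seed=config.seed
            )
            io.write_dwells(all_dwells, out / f"{_slug(label)}_dwells.tsv")
            io.write_json(matrix.to_dict(), out / f"{_slug(label)}_kinetics.json")
        agg = genotyping.aggregate_occupancy(occ_tables)
        per_allele[label] = {"occupancy": occ_tables, "aggregate": agg, "matrix": matrix}

    references = genotyping.load_reference_occupancies()
    calls = {
        label: genotyping.call_allele(entry["aggregate"], references)
        for label, entry in per_allele.items()
    }
    matrices = {l: e["matrix"] for l, e in per_allele.items() if e["matrix"] is not None}
    stability = genotyping.rank_stability(matrices) if matrices else None

    low_ranking = sorted(
        per_allele, key=lambda l: per_allele[l]["aggregate"].mean.get("low", 0.0), reverse=True
    )
    report = {
        "labels": labels,
        "per_allele": per_allele,
        "calls": calls,
        "stability": stability,
        "low_state_ranking": low_ranking,
    }
    io.write_json(_report_summary(report), out / "report.json")
    logger.info("pipeline complete; low-state ranking: %s", " > ".join(low_ranking))
    return report


def _obtain_path(config: RunConfig, label: str, models, seed: int) -> StatePath:
    if config.mode == "load":
        trace = io.read_trace(config.alleles[label])
        fit = idealization.fit_amplitude_histogram(trace, k_max=config.k_max)
        return idealization.idealize_trace(trace, fit, min_dwell_samples=config.min_dwell_samples)
    model_path = config.alleles.get(label)
    model = KineticModel.load(model_path) if model_path else models[label]
    logger.info("simulating %s with seed %d", label, seed)
    path = synthetic.simulate_state_path(model, config.n_exits, seed=seed)
    if config.idealize_from_trace:
        trace = synthetic.render_trace(path, model, seed=seed + 1)
        fit = idealization.fit_amplitude_histogram(trace, k_max=config.k_max)
        return idealization.idealize_trace(trace, fit, min_dwell_samples=config.min_dwell_samples)
    return path


def _slug(label: str) -> str:
    return label.replace("/", "_").replace(" ", "_")


def _report_summary(report: dict) -> dict:
    """JSON-safe summary shaped like the occupancy/kinetics reference tables."""
    occupancy_table = {}
    kinetic_table = {}
    for label, entry in report["per_allele"].items():
        agg = entry["aggregate"]
        occupancy_table[label] = {
            "mean_percent": agg.rounded(1),
            "sd_percent": {s: round(v, 1) for s, v in agg.sd.items()},
            "n_devices": agg.n_devices,
        }
        if entry["matrix"] is not None:
            kinetic_table[label] = entry["matrix"].to_dict()
    out = {
        "occupancy": occupancy_table,
        "kinetics": kinetic_table,
        "calls": {l: c.to_dict() for l, c in report["calls"].items()},
        "low_state_ranking": report["low_state_ranking"],
    }
    if report["stability"] is not None:
        st = report["stability"]
        out["stability"] = {
            "lifetime_order": st.lifetime_order,
            "unwinding_order": st.unwinding_order,
            "lifetimes_ms": {l: round(v, 3) for l, v in st.lifetimes.items()},
            "unwinding_probability": {l: round(v, 4) for l, v in st.unwinding.items()},
        }
    return out
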
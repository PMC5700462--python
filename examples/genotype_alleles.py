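"""Discriminate SNP alleles from simulated recordings of all four targets.

Simulates five replicate recordings per allele, aggregates their occupancies,
calls each profile against the bundled reference profiles, and ranks the
alleles by duplex (low-state) stability.
"""

from smfet import (
    aggregate_occupancy,
    call_allele,
    extract_dwells,
    kinetic_summary,
    load_reference_models,
    load_reference_occupancies,
    occupancy,
    rank_stability,
    simulate_state_path,
)

models = load_reference_models()
references = load_reference_occupancies()

matrices = {}
for i, (label, model) in enumerate(models.items()):
    paths = [simulate_state_path(model, 4_000, seed=10 * i + r) for r in range(5)]
    agg = aggregate_occupancy([occupancy(p) for p in paths])
    call = call_allele(agg, references)
    dwells = [d for p in paths for d in extract_dwells(p)]
    matrices[label] = kinetic_summary(dwells, seed=0)
    print(f"{label}: low state {agg.mean['low']:5.1f} +/- {agg.sd['low']:.1f} %  "
          f"-> called {call.label}")

report = rank_stability(matrices)
print("\nduplex lifetime order :", " > ".join(report.lifetime_order))
print("unwinding order       :", " > ".join(report.unwinding_order))
print("\nThe well-matched target (WT-C) keeps the probe in the duplex state "
      "far longer than any single-base mismatch; mismatches unwind straight "
      "to the single strand more often, MT-T most of all.\n"
      "Note: the occupancies implied by the reference kinetics differ from "
      "the measured reference profiles (missed events in real recordings), "
      "so the two middle mismatches (MT-A, MT-G) can swap labels in "
      "simulation — the well-matched vs mismatch separation is unambiguous.")
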
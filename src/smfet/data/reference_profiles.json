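{
  "description": "Published reference characterization of the rs1007616 hairpin-probe assay on single hairpin-DNA-decorated SiNW FET devices: per-device state occupancies and current levels from five representative recordings per target, the destination-resolved transition-probability/mean-lifetime matrices, and melting temperatures. Used as reference inputs for allele calling and as generative parameters for simulation; not produced by this package.",
  "states": ["low", "intermediate", "high"],
  "hairpin_sequence": "TGAGGATGGATAGATGCTTGCCTCA",
  "stem_length": 5,
  "measurement_temperature_C": 45.0,
  "sample_rate_kSa_s": 28.8,
  "filter_cutoff_kHz": 5.0,
  "occupancy": {
    "WT-C": {
      "device_percent": [[76.2, 21.7, 2.1], [79.6, 19.3, 1.1], [81.3, 17.9, 0.8], [79.2, 18.9, 1.9], [76.4, 23.1, 0.5]],
      "device_levels_nA": [[-3.09, 0.0, 3.19], [-2.86, 0.0, 2.91], [-2.56, 0.0, 2.85], [-2.73, 0.0, 3.08], [-2.95, 0.0, 3.23]],
      "avg_percent": [78.5, 20.2, 1.3],
      "avg_pm": [1.8, 1.8, 0.6]
    },
    "MT-A": {
      "device_percent": [[1.2, 90.4, 8.4], [3.5, 90.0, 6.5], [4.2, 89.6, 6.2], [4.9, 88.8, 6.3], [4.2, 90.8, 5.0]],
      "device_levels_nA": [[-1.35, 0.0, 1.36], [-1.70, 0.0, 2.21], [-2.29, 0.0, 1.46], [-1.53, 0.0, 1.68], [-2.09, 0.0, 1.79]],
      "avg_percent": [3.6, 90.0, 6.4],
      "avg_pm": [1.2, 0.8, 0.6]
    },
    "MT-G": {
      "device_percent": [[6.3, 70.6, 23.1], [5.2, 78.5, 16.3], [9.0, 72.5, 18.5], [8.1, 71.4, 20.5], [11.7, 68.5, 19.8]],
      "device_levels_nA": [[-1.21, 0.0, 1.33], [-1.95, 0.0, 2.12], [-2.10, 0.0, 1.52], [-1.32, 0.0, 1.75], [-1.98, 0.0, 2.08]],
      "avg_percent": [8.3, 72.0, 19.7],
      "avg_pm": [1.8, 2.6, 1.8]
    },
    "MT-T": {
      "device_percent": [[1.6, 92.7, 5.7], [1.5, 90.6, 7.9], [1.4, 88.4, 10.2], [1.6, 90.0, 8.4], [1.7, 90.8, 7.5]],
      "device_levels_nA": [[-1.38, 0.0, 1.25], [-2.14, 0.0, 2.40], [-2.37, 0.0, 1.56], [-1.59, 0.0, 1.39], [-2.23, 0.0, 1.89]],
      "avg_percent": [1.6, 90.5, 7.9],
      "avg_pm": [0.1, 1.0, 1.0]
    }
  },
  "kinetics": {
    "WT-C": {
      "P": [[0.0, 0.856, 0.144], [0.774, 0.0, 0.226], [0.191, 0.809, 0.0]],
      "tau_ms": [[0.0, 18.45, 25.03], [1.69, 0.0, 3.36], [0.86, 0.55, 0.0]],
      "tau_pm_ms": [[0.0, 1.36, 2.05], [0.16, 0.0, 0.57], [0.14, 0.09, 0.0]]
    },
    "MT-A": {
      "P": [[0.0, 0.697, 0.303], [0.386, 0.0, 0.614], [0.166, 0.834, 0.0]],
      "tau_ms": [[0.0, 8.97, 2.36], [47.16, 0.0, 49.16], [3.00, 8.13, 0.0]],
      "tau_pm_ms": [[0.0, 0.89, 0.60], [5.17, 0.0, 7.94], [0.14, 0.56, 0.0]]
    },
    "MT-G": {
      "P": [[0.0, 0.803, 0.197], [0.164, 0.0, 0.836], [0.177, 0.823, 0.0]],
      "tau_ms": [[0.0, 13.02, 5.66], [32.93, 0.0, 43.30], [2.63, 6.58, 0.0]],
      "tau_pm_ms": [[0.0, 2.01, 0.78], [2.73, 0.0, 3.57], [0.13, 0.45, 0.0]]
    },
    "MT-T": {
      "P": [[0.0, 0.597, 0.403], [0.225, 0.0, 0.775], [0.035, 0.965, 0.0]],
      "tau_ms": [[0.0, 2.89, 2.14], [44.86, 0.0, 45.64], [3.12, 4.73, 0.0]],
      "tau_pm_ms": [[0.0, 0.19, 0.09], [3.43, 0.0, 2.25], [0.37, 0.46, 0.0]]
    }
  },
  "melting": {
    "hairpin_tm_C": 46.5,
    "duplex_tm_C": {"WT-C": 59.6},
    "duplex_tm_order": ["WT-C", "MT-G", "MT-A", "MT-T"]
  }
}
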
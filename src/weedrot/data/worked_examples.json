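{
  "t2": {
    "kind": "opportunity_cost",
    "description": "Annual opportunity cost of switching BAU->MIT on HD-HR fields at current densities, from the published mean annual gross profits.",
    "units": "GBP/ha/yr",
    "inputs": {"gp_bau": 582.0, "gp_mit": 465.0},
    "expected": 117.0
  },
  "t3": {
    "kind": "productivity_cost",
    "description": "Annual productivity cost of switching BAU->MIT on HD-HR fields at current densities, from the published mean annual wheat yields.",
    "units": "t/ha/yr",
    "inputs": {"y_bau": 4.42, "y_mit": 2.39},
    "expected": 2.03
  },
  "t4": {
    "kind": "productivity_cost",
    "description": "Difference between BAU and MIT scenario-mean annual wheat yields across all 27 strategies.",
    "units": "t/ha",
    "inputs": {"y_bau": 4.6, "y_mit": 3.25},
    "expected": 1.35
  },
  "t5": {
    "kind": "percent_of_reference",
    "description": "Scaled-up annual wheat production loss for LD-HR fields as a share of annual UK domestic wheat consumption (~15 Mt).",
    "units": "%",
    "inputs": {"value": 1287734.0, "reference": 15000000.0, "ndigits": 1},
    "expected": 8.6
  },
  "t6": {
    "kind": "percent_of_reference",
    "description": "Scaled-up annual wheat production loss for HD-HR fields as a share of annual UK domestic wheat consumption (~15 Mt).",
    "units": "%",
    "inputs": {"value": 867055.0, "reference": 15000000.0, "ndigits": 1},
    "expected": 5.8
  },
  "t7": {
    "kind": "percent_of_reference",
    "description": "LD-HR per-hectare annual productivity cost as a share of the average English wheat yield (8.6 t/ha in 2022), to the nearest integer.",
    "units": "%",
    "inputs": {"value": 1.638, "reference": 8.6, "ndigits": 0},
    "expected": 19.0
  },
  "t8": {
    "kind": "switchable_mass",
    "description": "Share of grid cells below the top density state under the worst-case initial distribution, i.e. cells still able to move up.",
    "units": "%",
    "inputs": {"distribution": [0.1, 0.1, 0.2, 0.3, 0.3]},
    "expected": 70.0
  },
  "t9": {
    "kind": "relative_reduction",
    "description": "Relative reduction in the annual-mean proportion of a field at damaging density, MIT vs BAU.",
    "units": "%",
    "inputs": {"baseline": 0.5, "treatment": 0.2, "ndigits": 1},
    "expected": 60.0
  }
}
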
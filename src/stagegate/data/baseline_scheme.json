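{
  "schema_version": "1.0",
  "scheme": {
    "id": "cassava-east-africa-baseline",
    "market_segments": [
      {
        "client_features": {
          "farm size": "smallholder",
          "geographical region": "east Africa"
        },
        "environment_features": {
          "altitude": "lowland",
          "prevailing biotic stresses": "cassava mosaic disease",
          "water availability": "high rainfall"
        },
        "id": "ea-fresh",
        "product_features": {
          "end use": "fresh and flour",
          "maturity": "late",
          "shape": "long"
        }
      }
    ],
    "pipeline_id": "cassava-east-africa",
    "product_profiles": [
      {
        "segment_id": "ea-fresh",
        "traits": [
          {
            "bound": 25.0,
            "category": "output",
            "direction": "at_least",
            "name": "fresh yield",
            "unit": "t/ha"
          },
          {
            "bound": 30.0,
            "category": "quality",
            "direction": "at_least",
            "name": "dry matter",
            "unit": "%"
          },
          {
            "bound": 2.0,
            "category": "survival",
            "direction": "at_most",
            "name": "cassava mosaic disease",
            "unit": "score 1-5"
          },
          {
            "bound": 1.0,
            "category": "agronomic",
            "direction": "target_range",
            "name": "plant height",
            "unit": "m",
            "upper_bound": 3.0
          }
        ]
      }
    ],
    "segment_ids": [
      "ea-fresh"
    ],
    "stages": [
      {
        "crossing": {
          "allow_reciprocals": true,
          "coupling_method": "random",
          "extra": {},
          "n_crosses": 12,
          "n_parents": 4,
          "n_progeny_per_cross": 136
        },
        "evaluation": {
          "design_label": "",
          "extra": {},
          "n_checks": 0,
          "n_locations": 1,
          "plot_units": "m",
          "reps_per_location": 1
        },
        "name": "Crossing block",
        "selection": {
          "extra": {},
          "n_entries_in": 1632,
          "n_selected_out": 1632,
          "recycling_source": false,
          "selection_method": "truncation",
          "surrogate_of_merit": "phenotype"
        },
        "year": 1
      },
      {
        "evaluation": {
          "design_label": "nursery",
          "extra": {},
          "n_checks": 0,
          "n_locations": 1,
          "plot_units": "m",
          "reps_per_location": 1
        },
        "name": "Seedling nursery",
        "selection": {
          "extra": {},
          "n_entries_in": 1632,
          "n_selected_out": 1632,
          "recycling_source": false,
          "selection_method": "truncation",
          "surrogate_of_merit": "phenotype"
        },
        "year": 1
      },
      {
        "evaluation": {
          "design_label": "augmented",
          "extra": {},
          "n_checks": 0,
          "n_locations": 1,
          "plot_units": "m",
          "reps_per_location": 1
        },
        "name": "CE",
        "selection": {
          "extra": {},
          "n_entries_in": 1632,
          "n_selected_out": 120,
          "recycling_source": false,
          "selection_method": "truncation",
          "surrogate_of_merit": "phenotype"
        },
        "year": 2
      },
      {
        "evaluation": {
          "design_label": "RCBD",
          "extra": {},
          "n_checks": 0,
          "n_locations": 2,
          "plot_units": "m",
          "reps_per_location": 2
        },
        "name": "PYT",
        "selection": {
          "extra": {},
          "n_entries_in": 120,
          "n_selected_out": 64,
          "recycling_source": true,
          "selection_method": "truncation",
          "surrogate_of_merit": "phenotype"
        },
        "year": 3
      },
      {
        "evaluation": {
          "design_label": "RCBD",
          "extra": {},
          "n_checks": 0,
          "n_locations": 2,
          "plot_units": "m",
          "reps_per_location": 3
        },
        "name": "AYT",
        "selection": {
          "extra": {},
          "n_entries_in": 64,
          "n_selected_out": 24,
          "recycling_source": true,
          "selection_method": "truncation",
          "surrogate_of_merit": "phenotype"
        },
        "year": 4
      },
      {
        "evaluation": {
          "design_label": "RCBD",
          "extra": {},
          "n_checks": 0,
          "n_locations": 2,
          "plot_units": "m",
          "reps_per_location": 3
        },
        "name": "UYT",
        "selection": {
          "extra": {},
          "n_entries_in": 24,
          "n_selected_out": 24,
          "recycling_source": false,
          "selection_method": "truncation",
          "surrogate_of_merit": "phenotype"
        },
        "year": [
          5,
          6
        ]
      }
    ]
  }
}
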
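{
  "terms": {
    "biochemical_generic": {"label": "biochemical reaction", "id": 176},
    "transport_top": {"label": "translocation reaction", "id": 185},
    "exchange": {"label": "exchange reaction", "id": 627},
    "demand": {"label": "demand reaction", "id": 628},
    "sink": {"label": "sink reaction", "id": 632},
    "biomass": {"label": "biomass production", "id": 629},
    "transport_generic": {"label": "transport reaction", "id": 655},
    "transport_active": {"label": "active transport", "id": 657},
    "transport_passive": {"label": "passive transport", "id": 658},
    "transport_symport": {"label": "symporter-mediated transport", "id": 659},
    "transport_antiport": {"label": "antiporter-mediated transport", "id": 660},
    "species": {"label": "simple chemical", "id": 247},
    "species_macromolecule": {"label": "macromolecule", "id": 245},
    "gene": {"label": "gene", "id": 243},
    "modifier_enzymatic_catalyst": {"label": "enzymatic catalyst", "id": 460}
  },
  "energetic_moieties": {
    "atp": "atp",
    "adp": "adp",
    "phosphate": "pi",
    "pep": "pep",
    "pyruvate": "pyr"
  },
  "pts_sugar_pairs": {
    "glc__D": "g6p",
    "fru": "f6p",
    "man": "man6p",
    "mnl": "mnl1p",
    "acgam": "acgam6p"
  },
  "macromolecule_id_patterns": ["protein", "biomass", "dna", "rna"],
  "annotate_macromolecule_species": false
}
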
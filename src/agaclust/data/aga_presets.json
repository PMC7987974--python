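{
  "schema": "agaclust-aga-presets-v1",
  "comment": "Per-drug generative presets. 'efnext' maps inter-error distance d (correct residues between two errors) to the observable conditional next-error frequency anchored at that d; the generator back-solves the bound-state misreading probability m*w = efnext / q^(d+1). Entries with q_source 'assumed' are package choices (group-II drugs default to q = 0.5, the centre of the fitted 0.3-0.7 retention bracket); 'anchored' values reproduce published observables.",
  "group_ii_default_q": 0.5,
  "presets": {
    "Str": {
      "q": 0.97,
      "q_source": "anchored",
      "group": "I",
      "max_misreading_conc_um": 8,
      "efnext": {"1": 0.05, "2": 0.08}
    },
    "DHS": {
      "q": 0.97,
      "q_source": "assumed",
      "group": "I",
      "max_misreading_conc_um": 16,
      "efnext": {"1": 0.05}
    },
    "Par": {
      "q": 0.9,
      "q_source": "anchored",
      "group": "I",
      "max_misreading_conc_um": 8,
      "efnext": {"1": 0.09}
    },
    "Apr": {
      "q": 0.5,
      "q_source": "anchored",
      "group": "II",
      "max_misreading_conc_um": 16,
      "efnext": {"1": 0.25}
    },
    "Sis": {
      "q": 0.5,
      "q_source": "assumed",
      "group": "II",
      "max_misreading_conc_um": 8,
      "efnext": {"0": 0.4}
    },
    "KanA": {
      "q": 0.5,
      "q_source": "assumed",
      "group": "II",
      "max_misreading_conc_um": 16,
      "efnext": {"0": 0.36}
    },
    "group-II": {
      "q": 0.5,
      "q_source": "assumed",
      "group": "II",
      "max_misreading_conc_um": 8,
      "efnext": {"0": 0.4}
    }
  }
}
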
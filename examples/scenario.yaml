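# Example generator configuration: two councils, two annual rounds.
# Every knob of the synthetic-data model is listed with its default-style
# value; see docs/methods.md for what each one means.
councils:
  - {name: Ulari, region: Morning, n_dispensary: 30, n_health_center: 4, n_hospital: 1}
  - {name: Kivuli, region: Morning, n_dispensary: 45, n_health_center: 6, n_hospital: 2}
ownership_mix:
  public: 0.70
  faith_based: 0.15
  private: 0.10
  institutional: 0.05
# baseline yes-probability per quality dimension (1..6):
# motivation lowest, client satisfaction highest
q: {1: 0.75, 2: 0.55, 3: 0.70, 4: 0.70, 5: 0.40, 6: 0.85}
# per-round improvement increment per dimension
delta: {1: 0.02, 2: 0.05, 3: 0.03, 4: 0.03, 5: 0.06, 6: 0.01}
na_prob: 0.05
scenario_probs:
  under5_imci: 0.95
  pregnant: 0.80
  fever_over5: 0.90
  tb_hiv: 0.50
rounds: ["2011", "2012"]
# facility_effect_concentration: 12   # uncomment for facility heterogeneity
seed: 2011
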
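# Default plan-quality scoring configuration: 21 piecewise-linear metrics,
# maximum points summing to 150.  Metric names and clinical goals (target
# coverage 95/95/90/90 %, overall hotspot below 69 Gy, parotid V30Gy and mean
# dose, cord D0.03cc, oral cavity / esophagus / constrictor mean doses,
# brainstem and brachial-plexus near-maximum doses) follow standard
# head-and-neck plan-quality practice; the breakpoints are linear ramps
# between a full-credit and a zero-credit level chosen by this package.
#
# breakpoints: [metric value, points] pairs; scores are interpolated
# linearly and clamped at the extreme breakpoints.  Doses in cGy.

metrics:
  - {name: "V_PTV63[63Gy](%)",          structure: PTV63,            kind: volume_at_dose_pct, dose_cGy: 6300, max_points: 10, breakpoints: [[90, 0], [95, 10]]}
  - {name: "V_PTV60[60Gy](%)",          structure: PTV60,            kind: volume_at_dose_pct, dose_cGy: 6000, max_points: 10, breakpoints: [[90, 0], [95, 10]]}
  - {name: "V_PTV57[57Gy](%)",          structure: PTV57,            kind: volume_at_dose_pct, dose_cGy: 5700, max_points: 10, breakpoints: [[85, 0], [90, 10]]}
  - {name: "V_PTV54[54Gy](%)",          structure: PTV54,            kind: volume_at_dose_pct, dose_cGy: 5400, max_points: 10, breakpoints: [[85, 0], [90, 10]]}
  - {name: "D_Body[0.03cc](Gy)",        structure: BODY,             kind: dose_at_volume_cc,  volume_cc: 0.03, max_points: 10, breakpoints: [[6900, 10], [7200, 0]]}
  - {name: "V_ParotidL[30Gy](%)",       structure: "L Parotid",      kind: volume_at_dose_pct, dose_cGy: 3000, max_points: 5,  breakpoints: [[40, 5], [60, 0]]}
  - {name: "D_ParotidL[mean](Gy)",      structure: "L Parotid",      kind: mean_dose,          max_points: 5,  breakpoints: [[2600, 5], [3600, 0]]}
  - {name: "V_ParotidR[30Gy](%)",       structure: "R Parotid",      kind: volume_at_dose_pct, dose_cGy: 3000, max_points: 5,  breakpoints: [[40, 5], [60, 0]]}
  - {name: "D_ParotidR[mean](Gy)",      structure: "R Parotid",      kind: mean_dose,          max_points: 5,  breakpoints: [[2600, 5], [3600, 0]]}
  - {name: "D_cord[0.03cc](Gy)",        structure: Cord,             kind: dose_at_volume_cc,  volume_cc: 0.03, max_points: 5,  breakpoints: [[3500, 5], [4500, 0]]}
  - {name: "D_Brainstem[0.03cc](Gy)",   structure: Brainstem,        kind: dose_at_volume_cc,  volume_cc: 0.03, max_points: 10, breakpoints: [[3600, 10], [5400, 0]]}
  - {name: "D_Oral[mean](Gy)",          structure: "Oral Cavity",    kind: mean_dose,          max_points: 5,  breakpoints: [[3000, 5], [4500, 0]]}
  - {name: "D_Esophagus[mean](Gy)",     structure: Esophagus,        kind: mean_dose,          max_points: 5,  breakpoints: [[2000, 5], [3500, 0]]}
  - {name: "D_Constrictors[mean](Gy)",  structure: Constrictor,      kind: mean_dose,          max_points: 5,  breakpoints: [[4000, 5], [5500, 0]]}
  - {name: "D_BrachialPlexus[0.03cc](Gy)", structure: "Brachial Plexus", kind: dose_at_volume_cc, volume_cc: 0.03, max_points: 10, breakpoints: [[6300, 10], [6600, 0]]}
  - {name: "V_CTV63[63Gy](%)",          structure: CTV63,            kind: volume_at_dose_pct, dose_cGy: 6300, max_points: 10, breakpoints: [[95, 0], [99, 10]]}
  - {name: "V_CTV60[60Gy](%)",          structure: CTV60,            kind: volume_at_dose_pct, dose_cGy: 6000, max_points: 5,  breakpoints: [[95, 0], [99, 5]]}
  - {name: "V_CTV57[57Gy](%)",          structure: CTV57,            kind: volume_at_dose_pct, dose_cGy: 5700, max_points: 5,  breakpoints: [[95, 0], [99, 5]]}
  - {name: "V_CTV54[54Gy](%)",          structure: CTV54,            kind: volume_at_dose_pct, dose_cGy: 5400, max_points: 5,  breakpoints: [[95, 0], [99, 5]]}
  - {name: "D_PTV63[0.03cc](Gy)",       structure: PTV63,            kind: dose_at_volume_cc,  volume_cc: 0.03, max_points: 10, breakpoints: [[6700, 10], [7000, 0]]}
  - {name: "V_Body[50Gy](%)",           structure: BODY,             kind: volume_at_dose_pct, dose_cGy: 5000, max_points: 5,  breakpoints: [[25, 5], [40, 0]]}

# Which score-vector entries each adjustable priority slot influences; used
# to build the structure-coded vector fed to the action network.
tpp_metric_map:
  P1: ["V_ParotidL[30Gy](%)", "D_ParotidL[mean](Gy)"]
  P2: ["V_ParotidL[30Gy](%)", "D_ParotidL[mean](Gy)"]
  P3: ["V_ParotidR[30Gy](%)", "D_ParotidR[mean](Gy)"]
  P4: ["V_ParotidR[30Gy](%)", "D_ParotidR[mean](Gy)"]
  P5: ["D_Oral[mean](Gy)"]
  P6: ["D_Constrictors[mean](Gy)"]
  P7: ["D_Constrictors[mean](Gy)"]
  P8: ["D_BrachialPlexus[0.03cc](Gy)"]
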
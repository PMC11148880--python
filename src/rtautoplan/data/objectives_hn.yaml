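# Default head-and-neck inverse-planning objective template.
#
# 47 objectives over 26 planning structures: 20 lower dose-volume,
# 18 upper dose-volume, 9 mean-dose.  The first section is held fixed;
# the second section lists the objectives whose priorities the planning
# agent adjusts, sharing 8 priority slots P1..P8 (the three *_opti
# auxiliaries share the slot of their parent organ).
#
# dose_cGy: objective dose tau_i; volume_pct: V_i (dose-volume objectives
# only); priority: numeric weight lambda_i, or a P1..P8 placeholder.

priority_bounds: [1, 100]

initial_priorities:
  P1: 30
  P2: 30
  P3: 30
  P4: 30
  P5: 30
  P6: 40
  P7: 40
  P8: 50

objectives:
  # ---- fixed section -------------------------------------------------
  - {structure: PTV63,           dose_cGy: 6330, volume_pct: 99.9, priority: 90,  type: lower}
  - {structure: PTV63,           dose_cGy: 6380, volume_pct: 98,   priority: 90,  type: lower}
  - {structure: PTV60,           dose_cGy: 6030, volume_pct: 99.9, priority: 90,  type: lower}
  - {structure: PTV60,           dose_cGy: 6080, volume_pct: 98,   priority: 90,  type: lower}
  - {structure: PTV60,           dose_cGy: 6480, volume_pct: 0,    priority: 100, type: upper}
  - {structure: PTV57,           dose_cGy: 5750, volume_pct: 99.9, priority: 95,  type: lower}
  - {structure: PTV57,           dose_cGy: 5770, volume_pct: 99,   priority: 95,  type: lower}
  - {structure: PTV57,           dose_cGy: 5800, volume_pct: 98,   priority: 95,  type: lower}
  - {structure: PTV57,           dose_cGy: 6270, volume_pct: 0,    priority: 100, type: upper}
  - {structure: PTV54,           dose_cGy: 5450, volume_pct: 99.9, priority: 95,  type: lower}
  - {structure: PTV54,           dose_cGy: 5470, volume_pct: 99,   priority: 95,  type: lower}
  - {structure: PTV54,           dose_cGy: 5500, volume_pct: 98,   priority: 95,  type: lower}
  - {structure: PTV54,           dose_cGy: 5970, volume_pct: 0,    priority: 100, type: upper}
  - {structure: CTV63,           dose_cGy: 6330, volume_pct: 99.9, priority: 90,  type: lower}
  - {structure: CTV63,           dose_cGy: 6350, volume_pct: 99,   priority: 90,  type: lower}
  - {structure: CTV63,           dose_cGy: 6660, volume_pct: 0,    priority: 87,  type: upper}
  - {structure: CTV60,           dose_cGy: 6030, volume_pct: 99.9, priority: 90,  type: lower}
  - {structure: CTV60,           dose_cGy: 6050, volume_pct: 99,   priority: 90,  type: lower}
  - {structure: CTV60,           dose_cGy: 6500, volume_pct: 0,    priority: 100, type: upper}
  - {structure: CTV57,           dose_cGy: 5750, volume_pct: 99.9, priority: 93,  type: lower}
  - {structure: CTV57,           dose_cGy: 5770, volume_pct: 99,   priority: 93,  type: lower}
  - {structure: CTV57,           dose_cGy: 6270, volume_pct: 0,    priority: 100, type: upper}
  - {structure: CTV54,           dose_cGy: 5450, volume_pct: 99.9, priority: 95,  type: lower}
  - {structure: CTV54,           dose_cGy: 5470, volume_pct: 99,   priority: 95,  type: lower}
  - {structure: CTV54,           dose_cGy: 5940, volume_pct: 0,    priority: 100, type: upper}
  - {structure: PTV57_push,      dose_cGy: 5800, volume_pct: 99.9, priority: 98,  type: lower}
  - {structure: PTV54_push,      dose_cGy: 5500, volume_pct: 99.9, priority: 98,  type: lower}
  - {structure: PTV_all,         dose_cGy: 6500, volume_pct: 0,    priority: 80,  type: upper}
  - {structure: PTV-CTV63,       dose_cGy: 6500, volume_pct: 0,    priority: 80,  type: upper}
  - {structure: Brainstem,       dose_cGy: 2400, volume_pct: 0,    priority: 60,  type: upper}
  - {structure: Cord+5mm,        dose_cGy: 2600, volume_pct: 0,    priority: 63,  type: upper}
  - {structure: Esophagus,       dose_cGy: 1670,                   priority: 65,  type: mean}
  - {structure: Avoidance1,      dose_cGy: 5500, volume_pct: 0,    priority: 80,  type: upper}
  - {structure: Avoidance1,      dose_cGy: 3750,                   priority: 30,  type: mean}
  - {structure: Avoidance2,      dose_cGy: 5500, volume_pct: 0,    priority: 80,  type: upper}
  - {structure: Avoidance3,      dose_cGy: 5700, volume_pct: 0,    priority: 100, type: upper}
  # ---- adjustable section (priorities set by the planner) ------------
  - {structure: L Parotid,       dose_cGy: 3000, volume_pct: 0,    priority: P1,  type: upper}
  - {structure: L Parotid,       dose_cGy: 2750,                   priority: P2,  type: mean}
  - {structure: L Parotid_opti,  dose_cGy: 1850,                   priority: P2,  type: mean}
  - {structure: R Parotid,       dose_cGy: 3000, volume_pct: 0,    priority: P3,  type: upper}
  - {structure: R Parotid,       dose_cGy: 2750,                   priority: P4,  type: mean}
  - {structure: R Parotid_opti,  dose_cGy: 1250,                   priority: P4,  type: mean}
  - {structure: Oral Cavity_opti, dose_cGy: 2700,                  priority: P5,  type: mean}
  - {structure: Constrictor,     dose_cGy: 5650, volume_pct: 0,    priority: P6,  type: upper}
  - {structure: Constrictor,     dose_cGy: 3600,                   priority: P7,  type: mean}
  - {structure: Constrictor_opti, dose_cGy: 3400,                  priority: P7,  type: mean}
  - {structure: Brachial Plexus, dose_cGy: 6000, volume_pct: 0,    priority: P8,  type: upper}
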
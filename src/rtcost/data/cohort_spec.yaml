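# Packaged cohort specification: a 224-patient adjuvant breast radiotherapy
# cohort.  Groups give the baseline regimen assignment; role counts within
# each group encode the protocol-change transition each patient must
# undergo, and the generator forces exactly the covariates those
# transitions require.  Marginal targets are the audited cohort's
# patient-characteristics table; where a printed marginal is internally
# inconsistent with the printed total or with the transition counts, the
# transition counts are hard and the marginal is validated as soft
# (report-only) — see docs/methods.md.
seed: 20190107

groups:
  - regimen_id: 40-15_boost
    roles:
      boost_loser_ultra: 17
      boost_keeper_dibh_convert: 9
      boost_keeper_special_imn: 1
      boost_keeper: 26
      dcis_boosted: 5
  - regimen_id: 40-15
    roles:
      ultra: 26
      ultra_dibh_convert: 3
      dcis_gain: 4
      dcis_stay: 2
  - regimen_id: 40-15_boost_dibh
    roles:
      boost_loser_ultra: 12
      boost_keeper: 24
      dcis_boosted: 3
  - regimen_id: 40-15_dibh
    roles:
      ultra: 4
      dcis_gain: 1
      dcis_stay: 1
  - regimen_id: 40-15_scax_boost
    roles:
      boost_loser_nodal_stay: 5
      boost_keeper_imn_mover: 8
      boost_keeper_imn_mover_dibh_convert: 2
      boost_keeper_nodal_stay: 2
  - regimen_id: 40-15_scax
    roles:
      imn_mover: 16
      imn_mover_dibh_convert: 2
  - regimen_id: 40-15_scax_boost_dibh
    roles:
      boost_keeper_imn_mover: 4
      boost_keeper_nodal_stay: 1
  - regimen_id: 40-15_scax_dibh
    roles:
      imn_mover: 9
  - regimen_id: 40-15_scaximn_boost_dibh
    roles:
      boost_keeper: 6
  - regimen_id: 40-15_scaximn_dibh
    roles:
      plain: 7
  - regimen_id: 40-15_scaximn_boost
    roles:
      boost_keeper: 2
  - regimen_id: 40-15_scaximn
    roles:
      plain: 12
  - regimen_id: 50-25
    roles:
      ultra: 4
  - regimen_id: 50-25_dibh
    roles:
      ultra: 2
  - regimen_id: 50-25_scaximn_dibh
    roles:
      plain: 2
  - regimen_id: 50-25_scax_dibh
    roles:
      nodal_stay: 2

marginal_targets:
  sex: {"female": 221, "male": 3}
  t_stage: {"T0": 1, "Tis": 16, "T1": 95, "T2": 73, "T3": 34, "T4": 5}
  n_stage: {"N0": 120, "N1": 68, "N2": 18, "N3": 9, "NX": 9}
  chemotherapy: {"yes": 106, "no": 118}
  surgery: {"WLE": 150, "mastectomy": 74}
  reconstruction: {"yes": 11, "no": 213}
  nodal_surgery: {"none": 9, "SLNB": 155, "ALND": 60}
  laterality: {"left": 122, "right": 101, "bilateral": 1}
  central_or_medial: {"yes": 100, "no": 108}
  histology: {"DCIS": 16, "ductal": 163, "lobular": 25, "mixed": 7, "other": 13}
  molecular_subtype: {"luminalA": 124, "luminalB": 26, "HER2pos": 33, "triple_negative": 22}
  grade: {"1": 34, "2": 109, "3": 65}
  lvi: {"yes": 76, "no": 144}
  margin_positive: {"yes": 22, "no": 202}
  margin_le_2mm: {"yes": 25}
  dcis_nuclear_grade: {"low": 8, "high": 8}
  dcis_comedonecrosis: {"yes": 10, "no": 5}
  dcis_central_necrosis: {"yes": 6, "no": 9}
  dcis_symptomatic: {"yes": 11, "no": 4}

mean_age_target: 58.61

transition_targets:
  boost_removals_change_2: 34
  ultra_total_after_change_3: 68
  dcis_boost_additions_change_4: 5
  imn_additions_change_5: 42
  imn_total_after_change_5: 71
  final_counts:
    40-15_boost: 35
    40-15: 2
    40-15_boost_dibh: 37
    40-15_dibh: 1
    40-15_scax_boost: 2
    40-15_scax: 5
    40-15_scax_boost_dibh: 1
    40-15_scax_dibh: 2
    40-15_scaximn_boost_dibh: 12
    40-15_scaximn_dibh: 20
    40-15_scaximn_boost: 11
    40-15_scaximn: 28
    26-5: 47
    26-5_dibh: 21
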
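# Process map for one-week (26 Gy / 5 fraction) whole-breast radiotherapy,
# documented task by task from departmental interviews and recorded times.
# This is the reference pathway; pathways for other regimens are generated
# from the same template with the plan-design task calibrated per regimen
# (see rtcost.carepath.calibrated_carepath).
regimen_id: "26-5"
tasks:
  - {name: physician consultation, minutes: 30, role: physician, n_staff: 1, location: non_linac, frequency: per_course}
  - {name: simulation scan, minutes: 45, role: radiation_therapist, n_staff: 2, location: non_linac, frequency: per_course}
  - {name: contour OARs and transfer images, minutes: 40, role: radiation_therapist, n_staff: 1, location: non_linac, frequency: per_course}
  - {name: target volume delineation, minutes: 20, role: physician, n_staff: 1, location: non_linac, frequency: per_course}
  - {name: plan design, minutes: 90, role: radiation_therapist, n_staff: 1, location: non_linac, frequency: per_course}
  - {name: plan analysis, minutes: 35, role: physicist, n_staff: 1, location: non_linac, frequency: per_course}
  - {name: pre-treatment tasks, minutes: 35, role: radiation_therapist, n_staff: 1, location: non_linac, frequency: per_course}
  - {name: daily fraction, minutes: 15, role: radiation_therapist, n_staff: 2, location: linac, frequency: per_fraction}
  - {name: weekly chart check, minutes: 20, role: radiation_therapist, n_staff: 1, location: non_linac, frequency: per_treatment_week}
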
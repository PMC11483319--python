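# Annual salaries (EUR/year, Irish HSE-style 2023 pay scales, mid-scale
# points) and the annual worked-hours divisor (39-hour week net of leave).
# Config knobs: staff euros in the packaged pipeline come from the
# calibration fixture, not from these rates; they drive the care-path
# cross-check route only.
annual_working_hours: 1956
annual_salaries:
  physician: 172000
  radiation_therapist: 58812
  physicist: 85000
  other: 45000
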
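# Standard per-fraction linac appointment slots (minutes), keyed by nodal
# target volume and breathing technique.  Reconstructed so that slot x
# fractions reproduces every audited per-regimen linac-minutes total; DIBH
# slots are longer, and boost fractions are booked at the (none, matching
# breathing) slot.
slots:
  - {nodal_class: none, dibh: false, slot_minutes: 15}
  - {nodal_class: none, dibh: true, slot_minutes: 20}
  - {nodal_class: scax, dibh: false, slot_minutes: 15}
  - {nodal_class: scax, dibh: true, slot_minutes: 25}
  - {nodal_class: scax_imn, dibh: false, slot_minutes: 20}
  - {nodal_class: scax_imn, dibh: true, slot_minutes: 35}
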
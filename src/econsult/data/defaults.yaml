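# Default model parameters: elicited task timings (minutes), the observed
# submission category mix, note-use assumption, and staff unit costs (GBP).
timings:
  book_appointment: 3.0
  receive_econsult: 3.0
  close_off_with_contact: 3.0
  close_off_no_contact: 1.5
  face_to_face_appointment: 10.0
  telephone_consultation: 5.0
  process_minimal_notes: 2.5
  process_detailed_notes: 5.0
  sick_note: 4.0
  prescription_increment: 1.0
  other_followup_increment: 0.5
  change_of_details: 0.5
notes:
  detailed_fraction: 0.5
category_mix:
  admin_other_details: 0.12
  admin_fit_note: 0.15
  gp_no_action: 0.10
  gp_prescription: 0.20
  other_appointment: 0.13
  gp_phone_back: 0.15
  gp_appointment: 0.15
costs:
  gp_cost_per_hour: 95.08
  admin_cost_per_hour: 17.82
  conventional_booking_minutes: 3.0
  conventional_gp_minutes: 10.0
  annual_charge_per_patient: 0.63
induced_demand:
  induced_fraction: 0.08
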
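# Directed-marketing scenarios: category mixes achievable by steering
# patients toward submission types that replace a conventional appointment.
# declared_admin_share = details/other + fit note;
# declared_recall_share = other appointment + phone back + GP appointment
# (submissions whose outcome brings the patient back).
scenarios:
  - name: Base
    declared_admin_share: 0.27
    declared_recall_share: 0.43
    mix:
      admin_other_details: 0.12
      admin_fit_note: 0.15
      gp_no_action: 0.10
      gp_prescription: 0.20
      other_appointment: 0.13
      gp_phone_back: 0.15
      gp_appointment: 0.15
  - name: Scenario 1
    declared_admin_share: 0.40
    declared_recall_share: 0.30
    mix:
      admin_other_details: 0.15
      admin_fit_note: 0.25
      gp_no_action: 0.10
      gp_prescription: 0.20
      other_appointment: 0.10
      gp_phone_back: 0.10
      gp_appointment: 0.10
  - name: Scenario 2
    declared_admin_share: 0.35
    declared_recall_share: 0.25
    mix:
      admin_other_details: 0.15
      admin_fit_note: 0.20
      gp_no_action: 0.20
      gp_prescription: 0.20
      other_appointment: 0.10
      gp_phone_back: 0.10
      gp_appointment: 0.05
  - name: Scenario 3
    declared_admin_share: 0.30
    declared_recall_share: 0.20
    mix:
      admin_other_details: 0.10
      admin_fit_note: 0.20
      gp_no_action: 0.30
      gp_prescription: 0.20
      other_appointment: 0.05
      gp_phone_back: 0.10
      gp_appointment: 0.05
  - name: Scenario 4
    declared_admin_share: 0.20
    declared_recall_share: 0.15
    mix:
      admin_other_details: 0.05
      admin_fit_note: 0.15
      gp_no_action: 0.40
      gp_prescription: 0.25
      other_appointment: 0.05
      gp_phone_back: 0.05
      gp_appointment: 0.05
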
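# Illustrative run configuration with EXAMPLE tariff schedules.
#
# These unit costs are NOT authoritative reimbursement tariffs for any
# health system. They are synthetic, round-number examples with realistic
# relative magnitudes (invasive angiography above CMR, CABG above PCI,
# larger absolute tariffs in the Swiss and US systems) so the pipeline can
# be exercised end to end. Substitute your own payer's tariff schedule for
# any real analysis.
#
# Optional-item conventions mirrored here: rehabilitation after non-fatal
# MI is reimbursed in the German- and Swiss-style systems; the
# post-revascularization cardiologist visit in the German-, Swiss- and
# US-style systems.

cost_schedules:
  germany_example:
    currency: EUR
    c_cmr: 500
    c_cxa: 800
    c_ffr_addon: 150
    c_pci: 3000
    c_cabg: 12000
    c_nonfatal_mi: 4000
    c_stroke: 5000
    c_aborted_scd: 7000
    c_dual_antiplatelet_year: 350
    c_rehab_post_mi: 3000
    c_cardiologist_visit: 40
  uk_example:
    currency: GBP
    c_cmr: 350
    c_cxa: 1100
    c_ffr_addon: 300
    c_pci: 2500
    c_cabg: 8000
    c_nonfatal_mi: 3000
    c_stroke: 4000
    c_aborted_scd: 5000
    c_dual_antiplatelet_year: 300
  switzerland_example:
    currency: CHF
    c_cmr: 1300
    c_cxa: 2900
    c_ffr_addon: 800
    c_pci: 12000
    c_cabg: 40000
    c_nonfatal_mi: 15000
    c_stroke: 18000
    c_aborted_scd: 20000
    c_dual_antiplatelet_year: 700
    c_rehab_post_mi: 8000
    c_cardiologist_visit: 150
  us_example:
    currency: USD
    c_cmr: 800
    c_cxa: 1500
    c_ffr_addon: 700
    c_pci: 12000
    c_cabg: 30000
    c_nonfatal_mi: 15000
    c_stroke: 15000
    c_aborted_scd: 18000
    c_dual_antiplatelet_year: 800
    c_cardiologist_visit: 100

subgroups: [total, atypical_chest_pain, typical_angina]

variants:
  - name: main
    include_rehab: true
    include_cardiologist_visit: true
  - name: no_followup_items
    include_rehab: false
    include_cardiologist_visit: false

stenosis_ffr_anchors: [[0.35, 0.062]]
curve_interpolation: piecewise_linear

sweep:
  lo: 0.30
  hi: 0.55
  step: 0.05

sensitivity:
  parameters: [c_cmr, c_cxa, c_ffr_addon]
  relative_changes: [-0.10, 0.10]

breakeven:
  parameter: c_ffr_addon
  pairs: [[cxa_ffr, cxa_only]]

output_dir: out
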
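# Default chemistry panel: 17 serum analytes with reference intervals,
# within-subject biological variation (CVi), top-down analytical imprecision
# (CVa, largest of the per-instrument x per-level QC estimates), and the
# conventional per-setting delta-check rules of the source laboratory.
#
# CVg (between-subject biological variation) is deliberately left unset:
# the laboratory sourced CVi from the Westgard biological-variation database,
# which also lists CVg; supply cvg_percent here to enable index-of-
# individuality features.
#
# Rule methods: DD = delta difference (analyte units), DPC = delta percent
# change (%), RD = rate difference (units/day), RPC = rate percent change
# (%/day). Limits are signed: lower <= 0 <= upper.
analytes:
  - name: calcium
    units: mg/dL
    ref_low: 8.6
    ref_high: 10.2
    cvi_percent: 2.10
    cva_percent: 1.92
    conventional_rules:
      inpatient: {method: DD, upper: 1.3, lower: -1.3}
      outpatient: {method: DD, upper: 1.4, lower: -1.4}
  - name: glucose
    units: mg/dL
    ref_low: 70
    ref_high: 99
    cvi_percent: 5.60
    cva_percent: 2.23
    conventional_rules:
      inpatient: {method: DD, upper: 132, lower: -138}
      outpatient: {method: DD, upper: 145, lower: -152}
  - name: creatinine
    units: mg/dL
    ref_low: 0.70
    ref_high: 1.40
    cvi_percent: 5.95
    cva_percent: 4.59
    conventional_rules:
      inpatient: {method: DPC, upper: 50, lower: -35.87}
      outpatient: {method: DPC, upper: 55, lower: -39}
  - name: uric_acid
    units: mg/dL
    ref_low: 3
    ref_high: 7
    cvi_percent: 8.60
    cva_percent: 2.07
    conventional_rules:
      inpatient: {method: RD, upper: 0.83, lower: -1.17}
      outpatient: {method: RD, upper: 0.9, lower: -1.3}
  - name: cholesterol
    units: mg/dL
    ref_low: 0
    ref_high: 199
    cvi_percent: 5.95
    cva_percent: 1.95
    conventional_rules:
      inpatient: {method: RD, upper: 18, lower: -20}
      outpatient: {method: RD, upper: 20, lower: -22}
  - name: protein
    units: g/dL
    ref_low: 6
    ref_high: 8
    cvi_percent: 2.75
    cva_percent: 1.96
    conventional_rules:
      inpatient: {method: DD, upper: 1.3, lower: -1.5}
      outpatient: {method: DD, upper: 1.5, lower: -1.7}
  - name: albumin
    units: g/dL
    ref_low: 3.5
    ref_high: 5.2
    cvi_percent: 3.20
    cva_percent: 2.65
    conventional_rules:
      inpatient: {method: DD, upper: 0.8, lower: -0.9}
      outpatient: {method: DD, upper: 0.9, lower: -1.0}
  - name: ast
    units: U/L
    ref_low: 0
    ref_high: 40
    cvi_percent: 12.30
    cva_percent: 7.42
    conventional_rules:
      inpatient: {method: DPC, upper: 277.78, lower: -70.27}
      outpatient: {method: DPC, upper: 305, lower: -77}
  - name: alt
    units: U/L
    ref_low: 0
    ref_high: 40
    cvi_percent: 19.40
    cva_percent: 5.59
    conventional_rules:
      inpatient: {method: RPC, upper: 82, lower: -24.36}
      outpatient: {method: RPC, upper: 90, lower: -27}
  - name: alp
    units: U/L
    ref_low: 40
    ref_high: 120
    cvi_percent: 6.45
    cva_percent: 5.25
    conventional_rules:
      inpatient: {method: RPC, upper: 80, lower: -40}
      outpatient: {method: DPC, upper: 88, lower: -44}
  - name: total_bilirubin
    units: mg/dL
    ref_low: 0.2
    ref_high: 1.2
    cvi_percent: 21.80
    cva_percent: 2.24
    conventional_rules:
      inpatient: {method: DPC, upper: 200, lower: -66.67}
      outpatient: {method: DPC, upper: 220, lower: -73}
  - name: phosphorus
    units: mg/dL
    ref_low: 2.5
    ref_high: 4.5
    cvi_percent: 8.15
    cva_percent: 4.44
    conventional_rules:
      inpatient: {method: DD, upper: 2.1, lower: -2.2}
      outpatient: {method: DD, upper: 2.3, lower: -2.4}
  - name: bun
    units: mg/dL
    ref_low: 10
    ref_high: 26
    cvi_percent: 12.10
    cva_percent: 3.03
    conventional_rules:
      inpatient: {method: RPC, upper: 53.85, lower: -26.92}
      outpatient: {method: RPC, upper: 59, lower: -30}
  - name: direct_bilirubin
    units: mg/dL
    ref_low: 0
    ref_high: 0.5
    cvi_percent: 36.80
    cva_percent: 5.83
    conventional_rules:
      inpatient: {method: RPC, upper: 71.43, lower: -28.57}
      outpatient: {method: RPC, upper: 78, lower: -32}
  - name: sodium
    units: mEq/L
    ref_low: 135
    ref_high: 145
    cvi_percent: 0.60
    cva_percent: 1.05
    conventional_rules:
      inpatient: {method: DD, upper: 7, lower: -8}
      outpatient: {method: DD, upper: 8, lower: -9}
  - name: potassium
    units: mEq/L
    ref_low: 3.5
    ref_high: 5.1
    cvi_percent: 4.60
    cva_percent: 1.40
    conventional_rules:
      inpatient: {method: DD, upper: 1.2, lower: -1.2}
      outpatient: {method: DD, upper: 1.4, lower: -1.4}
  - name: chloride
    units: mEq/L
    ref_low: 98
    ref_high: 110
    cvi_percent: 1.20
    cva_percent: 1.51
    conventional_rules:
      inpatient: {method: DD, upper: 8, lower: -9}
      outpatient: {method: DD, upper: 9, lower: -10}
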
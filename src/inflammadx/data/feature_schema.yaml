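# Canonical 18-feature schema for inflammadx cohort tables.
# CSV input files must use exactly these column names plus a "diagnosis"
# label column. Units follow the clinical laboratory report conventions:
# mg/L for CRP, G/L (10^9/L) for absolute cell counts and platelets,
# g/dL for hemoglobin, % for differential fractions, and dimensionless
# relative MFI (median fluorescence intensity relative to the lymphocyte
# negative population) for the six flow-cytometry activation markers.
label_column: diagnosis
labels: [bacterial, viral, aid_gvhd, control]
features:
  - {name: CRP,             unit: mg/L, group: crp}
  - {name: WBC,             unit: G/L,  group: hemogram}
  - {name: Hemoglobin,      unit: g/dL, group: hemogram}
  - {name: Platelets,       unit: G/L,  group: hemogram}
  - {name: PMN_pct,         unit: "%",  group: hemogram}
  - {name: PMN_abs,         unit: G/L,  group: hemogram}
  - {name: Eosinophils_pct, unit: "%",  group: hemogram}
  - {name: Eosinophils_abs, unit: G/L,  group: hemogram}
  - {name: Basophils_pct,   unit: "%",  group: hemogram}
  - {name: Basophils_abs,   unit: G/L,  group: hemogram}
  - {name: Monocytes_pct,   unit: "%",  group: hemogram}
  - {name: Monocytes_abs,   unit: G/L,  group: hemogram}
  - {name: CD169_Mono,      unit: relative MFI, group: mfi}
  - {name: CD169_PMN,       unit: relative MFI, group: mfi}
  - {name: HLADR_Mono,      unit: relative MFI, group: mfi}
  - {name: HLADR_PMN,       unit: relative MFI, group: mfi}
  - {name: CD64_Mono,       unit: relative MFI, group: mfi}
  - {name: CD64_PMN,        unit: relative MFI, group: mfi}
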
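# Registry of tetraether lipid species detected in euxinic marine water
# columns, with their neutral molecular formulas and homologue-series
# relations.  A species either declares a formula directly or is derived
# from its parent by series steps (methylation +CH2, ring -H2, gmgt_bridge
# -H2).  nominal_mz is the declared integer [M+H]+ m/z used as an
# identification cross-check against the computed monoisotopic mass.
#
# Retention behaviour recorded in notes is metadata only; no peak picking
# is performed by this package.
species:
  - name: brGDGT-1a
    series_class: brGDGT
    formula: C66H132O6
    nominal_mz: 1022
    notes: >-
      Tetramethylated branched GDGT, no rings; the base species of the
      branched methylation series.
  - name: brGDGT-2a
    series_class: brGDGT
    parent: brGDGT-1a
    steps: [methylation]
    nominal_mz: 1036
  - name: brGDGT-2b
    series_class: brGDGT
    parent: brGDGT-1a
    steps: [methylation, ring]
    nominal_mz: 1034
  - name: brGDGT-3a
    series_class: brGDGT
    parent: brGDGT-1a
    steps: [methylation, methylation]
    nominal_mz: 1050
  - name: brGMGT-1a
    series_class: brGMGT
    parent: brGDGT-1a
    steps: [gmgt_bridge]
    nominal_mz: 1020
    notes: >-
      H-bridged (glycerol monoalkyl glycerol tetraether) counterpart of
      brGDGT-1a; under reverse-phase analysis elutes as a double peak
      (presumed isomers) about 0.4 and 0.7 min after brGDGT-1a.
  - name: OB-GDGT-9
    series_class: OB-GDGT
    parent: brGDGT-1a
    steps: [methylation, methylation, methylation, methylation, methylation]
    nominal_mz: 1092
    notes: >-
      Overly branched GDGT with nine methyl substituents in total; base of
      the OB methylation series (late eluting under reverse phase).
  - name: OB-GDGT-10
    series_class: OB-GDGT
    parent: OB-GDGT-9
    steps: [methylation]
    nominal_mz: 1106
  - name: OB-GDGT-11
    series_class: OB-GDGT
    parent: OB-GDGT-10
    steps: [methylation]
    nominal_mz: 1120
  - name: OB-GDGT-12
    series_class: OB-GDGT
    parent: OB-GDGT-11
    steps: [methylation]
    nominal_mz: 1134
  - name: isoGDGT-0
    series_class: isoGDGT
    formula: C86H172O6
    nominal_mz: 1302
    notes: Acyclic archaeal isoprenoid GDGT (caldarchaeol).
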
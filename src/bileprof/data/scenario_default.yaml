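# Default synthetic-study scenario: a 4-dose (75/150/300/600 mg/kg) x 3-replicate
# rat plasma bile-acid profiling study with planted ground truth, plus in-vitro
# liver-fraction incubations of nine standards.  Retention times of the library
# standards are synthetic but follow the tri-OH < di-OH < mono-OH elution order
# of a reversed-phase C18 gradient; isomer and sulfate-conjugate placements and
# fold changes anchor the pipeline's screening behaviour.
groups: ["75", "150", "300", "600"]
replicates: 3
analytical_cv: 0.10        # multiplicative (lognormal) peak-area noise
baseline_log_cv: 0.5       # per-compound baseline abundance spread (lognormal)
mass_ppm_sigma: 3.0        # mass-error scale, truncated at +/- mass_ppm_max
mass_ppm_max: 5.0
rt_jitter_sigma: 0.05      # minutes, truncated at +/- rt_jitter_max
rt_jitter_max: 0.10
lod: 500.0                 # features below this area are dropped
decoy_count: 15
decoy_mz_range: [350.0, 550.0]
decoy_exclusion_ppm: 25.0  # decoys stay this far from every target m/z
is_nominal_area: 50000.0
standard_baseline_area: 100000.0
isomer_baseline_area: 20000.0
conjugate_baseline_area: 30000.0
decoy_area: 8000.0
invitro_leakage: 0.0       # residual blocked-pathway signal in controls
invitro_parent_area: 500000.0
invitro_metabolite_area: 50000.0

# Standards from the 46-compound mix that are NOT detectable in plasma
# (13 compounds, leaving 33 identified standards).
absent_standards:
  [NUDCA, GLCA, di-oxo-LCA, 6-7-diketo-LCA, NCA, IDCA, AILCA, ILCA,
   DHCA, GDHCA, TDHCA, NDCA, DHLCA]

# 13 standards with planted dose effects: fold change of the 600 vs 75 mg/kg
# groups (dose response is log-linear in dose).
effects:
  DCA: 6.0
  HDCA: 6.4
  CA: 4.5
  ACA: 5.2
  GCA: 4.8
  GDCA: 4.2
  GHDCA: 5.5
  CDCA: 4.0
  UDCA: 4.3
  UCA: 4.6
  12-keto-DCA: 5.0
  7-keto-DCA: 4.4
  muro-CA: 4.1

# 22 planted isomers: library formulas at non-library retention times.
isomers:
  - {formula: C24H38O4, rt: 23.6, fc: 3.1}
  - {formula: C24H38O4, rt: 25.9, fc: 14.9}
  - {formula: C24H38O4, rt: 30.3, fc: 3.1}
  - {formula: C24H38O5, rt: 10.2, fc: 23.9}
  - {formula: C24H38O5, rt: 15.3, fc: 23.0}
  - {formula: C24H38O5, rt: 15.8, fc: 12.0}
  - {formula: C24H38O5, rt: 17.8, fc: 13.3}
  - {formula: C24H38O5, rt: 18.5, fc: 5.3}
  - {formula: C24H38O5, rt: 20.2, fc: 9.1}
  - {formula: C24H38O5, rt: 23.0, fc: 2.6}
  - {formula: C24H40O5, rt: 14.3, fc: 20.0}
  - {formula: C24H40O5, rt: 18.9, fc: 14.7}
  - {formula: C26H43NO6, rt: 6.7, fc: 6.1, msms_class: glycine}
  - {formula: C26H43NO6, rt: 8.4, fc: 8.9, msms_class: glycine}
  - {formula: C26H43NO6, rt: 9.5, fc: 14.0, msms_class: glycine}
  - {formula: C26H43NO6, rt: 10.8, fc: 5.6, msms_class: glycine}
  - {formula: C26H43NO6, rt: 11.8, fc: 8.0, msms_class: glycine}
  - {formula: C26H43NO5, rt: 13.8, fc: 20.5, msms_class: glycine}
  - {formula: C26H43NO5, rt: 19.4, fc: 8.0, msms_class: glycine}
  - {formula: C24H40O4, rt: 22.5, fc: 60.0}
  - {formula: C24H40O4, rt: 25.3, fc: 19.5}
  - {formula: C24H40O4, rt: 26.7, fc: 8.6}

# Phase-II conjugate features: 9 significant sulfates, 4 further sulfates and
# 6 glucuronides without dose effects (fc 1.0).  The GLCA+SO3 entry carries a
# taurine-type MS/MS spectrum: its formula C26H43NO7S equals a taurine
# conjugate of a keto-DCA-type core, and the spectrum forces re-annotation.
conjugates:
  - {parent: 7-keto-DCA, delta: sulfation, rt: 17.3, fc: 20.7}
  - {parent: CA, delta: sulfation, rt: 17.7, fc: 8.2}
  - {parent: 7-keto-LCA, delta: sulfation, rt: 21.6, fc: 5.9}
  - {parent: CDCA, delta: sulfation, rt: 21.6, fc: 8.5}
  - {parent: CDCA, delta: sulfation, rt: 23.9, fc: 6.3}
  - {parent: CDCA, delta: sulfation, rt: 25.3, fc: 6.9}
  - {parent: CDCA, delta: sulfation, rt: 26.5, fc: 6.5}
  - {parent: DHLCA, delta: sulfation, rt: 39.1, fc: 8.3}
  - {parent: LCA, delta: sulfation, rt: 41.8, fc: 14.0}
  - {parent: UDCA, delta: sulfation, rt: 19.5, fc: 1.0}
  - {parent: 12-keto-DCA, delta: sulfation, rt: 14.0, fc: 1.0}
  - {parent: CA, delta: sulfation, rt: 13.2, fc: 1.0}
  - {parent: GLCA, delta: sulfation, rt: 10.9, fc: 1.0, msms_class: taurine}
  - {parent: CA, delta: glucuronidation, rt: 9.6, fc: 1.0}
  - {parent: CDCA, delta: glucuronidation, rt: 14.9, fc: 1.0}
  - {parent: DCA, delta: glucuronidation, rt: 15.9, fc: 1.0}
  - {parent: UDCA, delta: glucuronidation, rt: 12.6, fc: 1.0}
  - {parent: LCA, delta: glucuronidation, rt: 24.9, fc: 1.0}
  - {parent: GCA, delta: glucuronidation, rt: 7.9, fc: 1.0}

# In-vitro incubation plans (liver S9, full cofactors vs no-NADP+ / no-PAPS
# controls).  Four metabolites (marked) elute at the retention time of a
# significant plasma isomer of the same formula and must cross-match.
invitro_plan:
  CA:
    - {delta: hydroxylation, rts: [9.8, 11.1]}
    - {delta: oxidation-to-keto, rts: [13.9]}
  alpha-MCA:
    - {delta: hydroxylation, rts: [6.4, 7.0, 7.8, 8.6]}
    - {delta: oxidation-to-keto, rts: [9.2]}
  beta-MCA:
    - {delta: hydroxylation, rts: [7.4, 8.1]}
    - {delta: oxidation-to-keto, rts: [9.9]}
  CDCA:
    - {delta: hydroxylation, rts: [16.2]}
    - {delta: sulfation, rts: [20.3]}
  DCA:
    - {delta: hydroxylation, rts: [12.5, 13.3, 15.1, 16.8, 17.5, 19.8, 21.2]}
    - {delta: dehydroxylation, rts: [30.8]}
    - {delta: oxidation-to-keto, rts: [15.8]}   # matches plasma keto-DCA isomer @ 15.8
    - {delta: sulfation, rts: [27.4]}
  UDCA:
    - {delta: hydroxylation, rts: [14.3, 10.9, 11.9, 13.1, 16.0]}  # 14.3 matches plasma CA isomer
    - {delta: sulfation, rts: [18.6]}
  LCA:
    - {delta: dihydroxylation, rts: [12.1, 13.6, 15.4, 16.3, 17.1, 19.9]}
    - {delta: hydroxylation, rts: [22.5, 24.0, 27.3, 28.2]}        # 22.5 matches plasma CDCA isomer
    - {delta: oxidation-to-keto, rts: [27.0]}
    - {delta: sulfation, rts: [33.2]}
  GCA:
    - {delta: oxidation-to-keto, rts: [11.5]}
  GCDCA:
    - {delta: hydroxylation, rts: [9.5, 5.9, 7.5, 10.2, 11.3, 12.4, 13.0]}  # 9.5 matches plasma GCA isomer
    - {delta: oxidation-to-keto, rts: [13.4, 14.6, 15.7, 16.8]}
    - {delta: dihydroxylation, rts: [5.2]}
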
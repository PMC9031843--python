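# Default synthetic cohort: 46 matched tumor/normal pairs (the validation
# cohort size), one planted ceRNA triplet with the published correlation
# magnitudes and qPCR fold changes for OIP5-AS1 / miR-203a / ZEB2.
n_tumor: 46
n_normal: 46
n_mirna: 5
n_lncrna: 10
n_mrna: 13
planted_triplets:
  - lncrna_id: OIP5-AS1
    mirna_id: miR-203a
    mrna_id: ZEB2
    rho_mi_lnc: -0.42
    rho_mi_mrna: -0.41
    rho_lnc_mrna: 0.65
    logfc_lncrna: 3.3
    logfc_mirna: -2.1
    logfc_mrna: 1.1
mirna_sequences:
  miR-203a: GUGAAAUGUUUAGGACCACUAG
plant_sites: true
site_type: 8mer
dispersion: 5.0
mean_log_expression: 6.0
dropout_rate: 0.05
ct_table:
  targets:
    miR-203a: [miRNA, -2.1]
    OIP5-AS1: [lncRNA, 3.3]
    ZEB2: [mRNA, 1.1]
  n_pairs: 46
  noise_sd: 0.2
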
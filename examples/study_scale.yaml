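# Study-scale synthetic run: 431 cases / 304 controls, the twelve-SNP
# candidate panel at the observed control allele frequencies, over-dominant
# exposure effects on the two instruments, null causal effect.
seed: 1
out_dir: telomr_run
model: over-dominant
k_strata: 5
n_boot: 500
thresholds:
  maf_min: 0.05
  hwe_alpha: 0.05
  exposure_alpha: 0.05
  screen_alpha: 0.05
screen_covariates: [age, sex_male, smoking, drinking, bmi, sbp, dbp,
                    fpg, tg, tc, hdl, ldl, apoa1, apob]
adjust_covariates: [age, sex_male]
simulation:
  n_cases: 431
  n_controls: 304
  exposure_mean: 1.9      # ln kb (about 6.7 kb)
  exposure_sd: 0.35
  causal_shape: "null"
  baseline_log_odds: 0.349
  snps:
    - {snp_id: rs11125529, maf: 0.1842, delta: -0.108, chromosome: "2", gene: ACYP2, ref_allele: C, alt_allele: A}
    - {snp_id: rs6772228, maf: 0.000, chromosome: "3", ref_allele: T, alt_allele: A}
    - {snp_id: rs10936599, maf: 0.4178, chromosome: "3", gene: MYNN, ref_allele: T, alt_allele: C}
    - {snp_id: rs7726159, maf: 0.3832, chromosome: "5", gene: TERT, ref_allele: C, alt_allele: A}
    - {snp_id: rs9420907, maf: 0.006, chromosome: "10", ref_allele: C, alt_allele: A}
    - {snp_id: rs17653722, maf: 0.1513, chromosome: "12", gene: KRT80, ref_allele: G, alt_allele: T}
    - {snp_id: rs3027234, maf: 0.042, chromosome: "17", ref_allele: C, alt_allele: T}
    - {snp_id: rs8105767, maf: 0.2714, chromosome: "19", ref_allele: A, alt_allele: G}
    - {snp_id: rs409627, maf: 0.3372, chromosome: "19", gene: ZNF676, ref_allele: G, alt_allele: C}
    - {snp_id: rs412658, maf: 0.3372, delta: -0.089, chromosome: "19", gene: ZNF676, ref_allele: C, alt_allele: T}
    - {snp_id: rs6028466, maf: 0.002, chromosome: "20", ref_allele: A, alt_allele: T}
    - {snp_id: rs755017, maf: 0.4227, chromosome: "20", gene: ZBTB46, ref_allele: A, alt_allele: G}
  covariates:
    - {name: age, kind: continuous, mean: 53.0, sd: 14.0, beta_exposure: -0.002, beta_outcome: 0.06}
    - {name: sex_male, kind: binary, prevalence: 0.51, beta_outcome: 0.55}
    - {name: smoking, kind: binary, prevalence: 0.32, beta_outcome: 0.9}
    - {name: drinking, kind: binary, prevalence: 0.36, beta_outcome: 0.4}
    - {name: bmi, kind: continuous, mean: 25.0, sd: 3.3, beta_outcome: 0.05}
    - {name: sbp, kind: continuous, mean: 131.0, sd: 16.0, beta_outcome: 0.03}
    - {name: dbp, kind: continuous, mean: 81.0, sd: 11.0, beta_outcome: 0.01}
    - {name: fpg, kind: continuous, mean: 5.3, sd: 1.1, beta_outcome: 0.10}
    - {name: tg, kind: continuous, mean: 1.5, sd: 0.8, beta_outcome: 0.10}
    - {name: tc, kind: continuous, mean: 4.4, sd: 0.8, beta_outcome: -0.15}
    - {name: hdl, kind: continuous, mean: 1.15, sd: 0.25, beta_outcome: -1.0}
    - {name: ldl, kind: continuous, mean: 2.5, sd: 0.7, beta_outcome: 0.05}
    - {name: apoa1, kind: continuous, mean: 1.22, sd: 0.16, beta_outcome: -0.8}
    - {name: apob, kind: continuous, mean: 0.95, sd: 0.25, beta_outcome: -0.4}
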
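# Example study configuration.
#
# Runnable as-is against the synthetic fixture suite:
#     mrmediate fixtures --out fixtures
#     mrmediate run examples/study_config.yaml
#
# For a real drug-target study, replace each exposure's `gwas` with the
# downloaded biomarker summary statistics (LDL-C for LDLR/HMGCR/NPC1L1/
# PCSK9/APOB/ABCG5/ABCG8, triglycerides for LPL/APOC3/PPARA), `region`
# with the target gene's span (mrmediate.instruments.DRUG_TARGET_REGIONS
# lists the ten GRCh37 spans), `ld` with an r² matrix over the cis SNPs
# from your reference panel, the outcome with the AF (or CHD positive
# control) GWAS, and `mediators` with the 91 inflammation-protein pQTL
# files. Set m_exposures: 10 and m_mediators: 91 to keep the Bonferroni
# families defined by the screened sets.

seed: 1
output_dir: results_example

p_exposure: 5.0e-8
p_mediator: 5.0e-6
eaf_min: 0.01
r2: 0.3
r2_fallback: 0.4
min_snps: 3
clump_kb: 10000
n_boot: 1000
n_sim: 1000
estimator_mode: auto
palindrome_policy: infer-by-frequency
overlap_policy: drop-shared
m_exposures: 1
m_mediators: 1
# blocklist: confounder_snps.tsv   # two columns: snp_id, trait

exposures:
  - name: LPL
    gwas: ../fixtures/mediation_p09/exposure.tsv
    ld: ../fixtures/mediation_p09/ld.tsv
    region:
      gene_symbol: GENE1
      chrom: "1"
      start: 1000000
      end: 1050000
      flank_kb: 100

outcome:
  name: AF
  gwas: ../fixtures/mediation_p09/outcome.tsv

mediators:
  - name: FGF5
    gwas: ../fixtures/mediation_p09/mediator.tsv
    ld: ../fixtures/mediation_p09/ld.tsv
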
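"""Check that imputation preserves protein-complex co-expression.

Proteins in one complex co-vary; random protein pairs should not. The
report compares within-complex Spearman correlations to an equally sized
random background, before and after model-based imputation — a good
imputer keeps the within-complex signal high and the background near zero
(i.e., it does not hallucinate correlations).
"""

import lupine as lp

spec = lp.SimSpec(n_cohorts=1, proteins_per_cohort=300, samples_per_cohort=60,
                  paired_patients_per_cohort=30, shared_protein_fraction=1.0,
                  latent_rank=50, plex_offset_sd=0.05, cohort_offset_sd=0.0,
                  n_de_proteins=0, n_complexes=15, complex_size=6,
                  complex_loading=0.8, target_missing_fraction=0.30, seed=55)
observed, truth = lp.simulate_cohorts(spec)

before = lp.complex_correlations(observed, truth.complexes,
                                 pre_imputation=observed, seed=9)
print(f"before imputation: within {before.mean_within:+.3f} vs "
      f"background {before.mean_background:+.3f} over {before.n_pairs} pairs")

masks = lp.mnar_partition(observed, lp.PartitionParams(seed=10))
config = lp.ModelConfig(n_protein_factors=16, n_sample_factors=16,
                        n_hidden_layers=1, n_nodes_per_layer=64, max_epochs=200)
result = lp.fit_ensemble(observed, masks, n_models=2, seed=12, configs=[config] * 2)
completed = lp.impute_matrix(observed, result.averaged_prediction)

after = lp.complex_correlations(completed, truth.complexes,
                                pre_imputation=observed, seed=9)
print(f"after imputation:  within {after.mean_within:+.3f} vs "
      f"background {after.mean_background:+.3f} (p = {after.p_value:.1e})")
print("within-complex correlations stay high and the background stays ~0, "
      "so imputation is not introducing spurious protein-protein structure")
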
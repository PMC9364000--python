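"""Generate a synthetic paired winter/summer methylation cohort.

Builds the default study design — 20 individuals, 15 sampled in both
seasons, 30% wild-caught with minimum ages — and a 2000-probe beta matrix
with planted age trends at clock sites and seasonal offsets at DMP sites.
"""

from hibernaclock import SyntheticConfig, generate_beta_matrix, generate_cohort

config = SyntheticConfig(seed=1)
cohort = generate_cohort(config)
betas, truth = generate_beta_matrix(cohort, config)

print(cohort.head(6).to_string(index=False))
print(f"\n{len(cohort)} samples from {cohort['individual_id'].nunique()} "
      f"individuals; {int(cohort.groupby('individual_id').size().eq(2).sum())} "
      "complete winter/summer pairs")
print(f"beta matrix: {betas.shape[0]} probes x {betas.shape[1]} samples, "
      f"values in [{betas.values.min():.3f}, {betas.values.max():.3f}]")
print(f"planted truth: {len(truth.clock_site_ids)} clock sites, "
      f"{len(truth.dmp_sites)} DMP sites "
      f"({(truth.dmp_sites['true_direction'] == 'winter-up').mean():.1%} "
      "winter-up), seasonal age offset "
      f"{truth.planted_seasonal_offset} years")
# Each row of the sample sheet is one wing-biopsy sample; age_is_minimum
# flags wild-caught animals whose recorded age is only a lower bound.
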
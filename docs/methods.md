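# Methods

## The synthetic cohort model

The generator emulates a captive colony of a hibernating bat species with
paired seasonal sampling. Defaults (all overridable in `SyntheticConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| `n_individuals` | 20 | animals | colony-scale study |
| `frac_paired` | 0.75 | — | 15 of 20 animals sampled in both seasons |
| `frac_wild` | 0.30 | — | wild-caught animals with minimum ages only |
| `age_range` | (0.7, 10.1) | years | first decade of life |
| `n_probes` | 2000 | CpG sites | tractable stand-in for a ~37 k array |
| `n_clock_sites` | 50 | CpG sites | sites with linear age trends |
| `n_dmp_sites` | 100 | CpG sites | sites with seasonal offsets |
| `frac_winter_up` | 0.775 | — | winter-up excess among planted DMPs |
| `dmp_effect_mean` | 0.10 | beta units | 5× the noise SD, clearly detectable |
| `noise_sd` | 0.02 | beta units | typical array-replicate noise scale |
| `individual_sd` | 0.01 | beta units | within-individual correlation across seasons |
| `age_slope_sd` | 0.01 | beta / year | ~0.1 beta change across the age range |
| `seasonal_age_offset` | 0.77 | years | planted winter epigenetic-age deceleration |

Per probe *i* and sample *s* the beta value is

```
β_is = b_i + m_i (a_s − δ·w_s)·[clock site]
           + e_i w_s·[DMP site] + u_{i,ind(s)} + ε_is,   clipped to [0,1]
```

with baseline `b_i ~ U(0.15, 0.85)`, clock slope `m_i ~ N(0, age_slope_sd)`,
winter indicator `w_s`, planted offset δ = `seasonal_age_offset`, DMP effect
`e_i = ±|N(dmp_effect_mean, dmp_effect_sd)|` (sign by planted direction),
individual random intercept `u ~ N(0, individual_sd)` and truncated-Gaussian
noise `ε ~ N(0, noise_sd)`. Noise is added on the beta scale (the analysis
operates on beta values directly, not M-values); clipping counts are logged
and a warning is raised when clipping touches more than 10% of entries.
Implementing the winter clock-site shift as `−m_i·δ` makes the planted
epigenetic-age deceleration exactly δ years, giving a known truth for the
seasonal test. Wild-born individuals' recorded ages are their true ages
minus a positive censoring offset (uniform 0.5–2 years) and carry a
minimum-age flag. Summer samples are taken five months after winter
samples, so true age differs between an individual's two samples.

Probe-level biology (baselines, slopes, effects, the toy genome, gene sets,
element maps) is keyed by `probe_seed`, distinct from the cohort seed, so a
clock-training cohort and a study cohort can share one "array". All
randomness flows through `numpy` generators seeded per component; a fixed
configuration reproduces every output byte for byte.

What the generator does **not** emulate: bisulfite-chemistry or
probe-hybridization noise structure, plate/batch effects, normalization
artefacts, cell-type composition shifts, CpG-island structure, or realistic
LD-like spatial correlation of methylation beyond the proximity of planted
probes. Passing recovery tests therefore demonstrate the statistical
machinery is correct under the planted model, not that real-array
preprocessing issues are handled.

## Epigenetic clock

`fit_clock` minimizes the elastic-net objective
`(1/2n)‖y − Xw − b‖² + λα‖w‖₁ + (λ(1−α)/2)‖w‖²` with mixing α = 0.5 and λ
chosen by k-fold cross-validated MSE on a 100-point λ path (the minimizing
λ, not the 1-SE rule — simpler and reproducible). Folds are shuffled under
the supplied seed. Samples with minimum ages should be excluded from
training (the pipeline does) but are predicted like any other.

Age acceleration is the residual from OLS of predicted on chronological
age over the supplied prediction set — not `predicted − chronological` —
so residuals are orthogonal to age and sum to zero. Accuracy metrics are
the r² of that regression and the **median** absolute error in years.

`test_season_effect` fits `residual ~ season + birthplace + (1|individual)`
by REML (statsmodels `MixedLM`) and reports Wald F-tests (1 numerator df)
with containment denominator df: season, a within-individual effect, is
tested on `N − n_individuals − 1` df (equal to `n_pairs − 1` in a fully
paired design, where the test is exactly the paired t-test); birthplace, a
between-individual effect, on `n_individuals − 2` df. Winter is coded 1,
so a negative effect means hibernating samples are epigenetically younger.
Numerical notes: the L-BFGS optimizer runs with tight tolerances
(`factr=10`, `pgtol=1e-12`) so the paired-t equivalence holds to ~1e-8 in
p; when the individual variance collapses to the boundary and the
information matrix turns singular, the fit falls back to derivative-free
Powell, then Nelder–Mead. If the within-individual differences carry no
variance at all (degenerate zero-noise designs) the Wald test is a point
mass and is returned in closed form.

The seasonal deceleration recovered through a *fitted* clock is mildly
attenuated and noisy relative to the planted δ: penalized weights shrink
the age slope, and seasonal DMP sites that leak small weights into the
clock add between-seed variance. This mirrors real clock-based
age-acceleration estimates and is why the recovery criterion is framed in
standard errors rather than as a point match.

## DMP detection

Age adjustment pools all samples (both seasons) in one OLS of beta on age
per probe, vectorized as a single least-squares solve across the matrix;
an option restricts the baseline to summer samples for sensitivity
analysis. The seasonal test uses the exact equivalence, on complete pairs,
between the random-intercept REML model and the paired t-test on
within-individual winter − summer differences; this vectorizes across all
probes at array scale. The explicit per-probe `MixedLM` path
(`method="reml"`) exists as a reference and is oracle-tested to agree to
1e-6. Probes with fewer than 3 complete pairs are reported untested
(p = 1, flagged); a probe with zero contrast gets p = 1 and direction
`none`. The standardized effect z-scores a probe's residuals before the
paired comparison, giving a scale-free coefficient comparable across
probes.

BY adjustment is delegated to `statsmodels.multipletests(method="fdr_by")`
behind the `by_fdr` surface and verified against a brute-force evaluation
of the step-up formula. Directions are called at BY p < threshold (default
0.05) by coefficient sign. The direction summary includes a 50:50
goodness-of-fit χ² for the winter-up excess; note that published
direction-imbalance statistics computed under other null proportions will
not match this 50:50 test.

## Genomic annotation

Coordinates are 0-based half-open (BED conventions in exported files).
The nearest gene is the gene with the closest TSS on the probe's scaffold,
ties broken toward the lexicographically smaller gene id. Signed distance
is strand-aware (negative = upstream). Region classes are assigned by
precedence — promoter > 5′UTR > 3′UTR > exon > intron > intergenic — with
the promoter window closed at both ends, [−10 000, +1 000] bp around the
nearest TSS. Containment is evaluated only against the nearest gene's
model, so a probe inside another (non-nearest) gene's exon can classify by
its nearest gene's geometry; this is a deliberate consequence of
nearest-TSS-based classification. Probes on geneless scaffolds are
intergenic with no distance.

Region enrichment compares observed DMP counts per region with
expectations proportional to the array background. The per-region
statistic is the single-cell deviation (O−E)²/E with 1 df; the omnibus
statistic is their sum over regions with (#regions − 1) df. TSS-distance
comparisons use the pooled-variance two-sample Student's t on absolute
distances.

## Element and gene-set enrichment

The permutation test thins the DMP set greedily left-to-right by genomic
coordinate so no two retained sites lie within `proximity_bp` (default
1000), then compares its overlap with each element map against random
same-size thinned draws from the array background (probes visited in
random order, kept unless within the window of a kept probe). Sampling is
uniform over the background — a deliberate simplification of
matched-background sampling on gene/CpG-island annotation, whose metadata
is out of scope here. Empirical p-values use the add-one rule
`(1 + #{perm ≥ obs})/(1 + n_perm)`, so they are never zero, and are
BY-adjusted across maps (significance threshold 1% by default). Note that
with m maps and n permutations the smallest attainable BY-adjusted p is
`m·c(m)/(n+1)`; detecting enrichment at BY p < 0.01 across many maps
requires permutation counts in the thousands.

Gene directions follow the majority rule over a gene's DMPs (ties →
`none`). Overlap tests build the 2×2 table on the full gene background;
the χ² statistic is Pearson's without continuity correction, and the
Fisher p sums hypergeometric probabilities of all tables no more probable
than the observed one (two-sided convention), with a 1e-7 relative
tolerance when comparing table probabilities to absorb float noise.

## Pipeline

`run_pipeline` derives per-stage seeds from the master seed by a stable
CRC32 hash of the stage name, so stages can be rerun independently yet
reproducibly, and keeps every seed below 2³¹. The clock stage trains on a
separate synthetic known-aged, active-season reference cohort (60
individuals by default) sharing the study cohort's probe biology — the
analogue of applying an externally trained species clock. Any stage
failure aborts the run with the stage named; completed outputs and a
partial `summary.json` are retained. Timings in `summary.json` are the
only non-reproducible bytes; all analysis tables are byte-identical under
a fixed seed.

Default problem sizes (2000 probes, 20 + 60 individuals, 100–1000
permutations, 3–20 seeds in the recovery experiments) were chosen so the
full test suite and the acceptance script each run in well under ten
minutes on a single CPU while keeping every recovery margin comfortable.

## Known limitations

- The elastic-net λ path and CV-fold shuffling make selected site sets
  seed-dependent; only predictions, not coefficient identities, are stable
  targets.
- The paired-difference fast path requires complete pairs; individuals
  sampled in one season inform age adjustment and prediction but not the
  per-probe seasonal test.
- The containment-df rule is one of several defensible choices
  (Satterthwaite would differ in unbalanced designs); published analyses
  may report different denominator df for between-individual effects.
- Uniform-background permutation sampling ignores probe annotation
  matching; enrichment p-values on real arrays with strong annotation
  structure would be anti-conservative.
- The generator's clipping at [0, 1] slightly biases planted effects at
  extreme baselines; effect recovery tests use moderate baselines where
  clipping is negligible.
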
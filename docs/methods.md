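# Methods

This note documents the models behind `evoreseq`, the parameter choices
that matter, the conventions of the statistical procedures, and what the
synthetic-data generator does and does not emulate.

## The simulated experiment

`simgen` models a mutagenize-then-evolve fly experiment as four layers.

**Founders.** A cohort of `n_founders` diploids carries two classes of
variation on a linear genome partitioned into chromosomes proportional to
the five major *D. melanogaster* arms (X, 2L, 2R, 3L, 3R; positions are
all that downstream windowing needs, so no sequence is represented).
*Standing variants* (`n_sites_standing`) have population frequencies drawn
from `Beta(α, β)` (default `Beta(2, 2)`: a lab stock kept at moderate size
holds mostly intermediate-frequency variants; extreme rare frequencies are
underrepresented) and founder genotypes `Binomial(2, p)`. *EMS mutations*
enter each founder as a Poisson draw with mean `ems_rate_per_mb ×
genome_size_mb` (default 2.7/Mb over 180 Mb), at uniform positions,
heterozygous in exactly one founder — mutagenized males were outcrossed,
so every induced mutation arrives in a single copy.

**Evolution.** Each of `n_populations` (default 18) populations evolves by
Wright–Fisher resampling of `2N` allele copies per generation (default
`N = 300`, within the stated 200–500 census range; configurable). A site
with selection coefficient `s` first moves to `p' = p(1+s)/(1+ps)` — genic
multiplicative selection on the alternative allele, the simplest standard
choice since no fitness model is stated for the original experiment.
Sites assort independently (no recombination, no linkage): linkage only
matters to the pruning step of the mutation-rate estimator, and the tests
that exercise pruning construct correlated sites explicitly by copying
genotypes. There is no recurrent mutation, so frequencies absorb at 0
and 1. A `deterministic` mode disables sampling for fixed-point tests.

**Pooled sequencing.** Per-site coverage is negative binomial with mean
`mean_depth` and dispersion `φ` (variance `m + φ m²`; Poisson at `φ = 0`).
The defaults (mean 29, `φ = 1.0`) reproduce the mean-29 / median-21
coverage profile of shallow pooled resequencing. Alternative depth is
`Binomial(coverage, p)`; sequencing error is not modelled.

**Phenotypes.** Embryo length is `baseline + Σ effect × dosage + ε`,
with `ε ~ N(0, 15 µm)` and per-embryo dosages `Binomial(2, p_site)`. The
550 µm default baseline is the ancestral median egg length; the evolved
regime is reached by raising the baseline (e.g. to the observed 567 µm)
or through configured per-site effects. Scaled stripe positions (% egg
length, anterior = 0) are anchored at a fixed reference length (550 µm)
and respond to embryo length through a coupling of −0.065 %EL/µm — the
observed ~1.1 %EL anterior stripe shift divided by the observed ~17 µm
length increase — plus `N(0, 1.2 %EL)` stripe noise. The 1.2 value is
derived from the reported 95% confidence interval of the stripe-1
position (37.2 ± 0.4 %EL at n = 60 → total SD ≈ 1.6 %EL) after removing
the variance the length coupling itself contributes (0.065 × 15 µm ≈
1 %EL). Nuclei are laid down along the A-P axis at a mean spacing of
6.5 µm (the observed 6.4–6.8 µm range) with jitter.

All randomness descends from `SimConfig.seed` through tagged
`SeedSequence` streams: an identical config reproduces the bundle
bit-for-bit, and a generation's pooled reads are identical whether that
generation is sampled alone or in a batch.

## Analysis conventions

**Mutation-rate estimation** applies its filters in a fixed order:
(1) indel sites removed; (2) genotypes with depth outside `[4, 50]`
(inclusive bounds) masked to missing; (3) sites whose mean depth over the
remaining genotypes falls outside the same band removed; (4) sites
missing in more than 2 individuals removed. The operation is idempotent.
Linkage pruning is a greedy left-to-right scan per chromosome: a site is
dropped when its dosage vector has squared Pearson correlation > 0.6
(pairwise-complete, monomorphic pairs count as r² = 0) with an
already-retained site ≤ 1 kb upstream; greedy first-kept scanning is
deterministic and order-stable where windowed pruning tools leave
tie-breaking unspecified. A private mutation is a site whose minor allele
has cohort allele count exactly 1 — one heterozygote, carrying either the
alternative or the reference as the minor allele — with ≥ 3 reads
supporting that allele. Rates are per-individual counts over covered
megabases (an input column; a helper computes it from per-base depths
with the same band); the summary mean is unweighted over mutagenized
individuals only, with non-mutagenized flies reported as background and
never entering the mean. The displayed cohort mean count is rounded to
the nearest integer.

**Recurrence scan.** The allele-depth Fisher test excludes a site-
population pair when either generation's depth is < 10 or the alternative
depth is < 2 in *both* generations (the gate is one-sided: depth 2 in a
single generation suffices, since an allele absent early and present late
is exactly the signal sought). The two-sided p-value uses the
probability-mass convention — the sum of hypergeometric probabilities of
tables no more probable than the observed table — implemented on
precomputed log-factorials for throughput (the scans run hundreds of
thousands of tables); masses within a relative 1e-7 of the observed mass
count as ties, as in the standard R implementation, and totals within
1e-12 of 1 are snapped to exactly 1 so equal-ratio tables report p = 1.
The test suite checks this kernel against exact integer enumeration for
every 2×2 table with total ≤ 60 and against scipy. FDR adjustment is
Benjamini–Hochberg, applied within each population by default (mirroring
per-population tool invocations; a global scope is available). A
directional call requires q < 0.05 *and* a strict change in the raw
reference-depth fraction; exact ties call `none` (a significant p with
equal fractions cannot occur for 2×2 tables). Excluded populations
contribute an implicit `none` to the sign score. The recurrence report
counts sites significant in ≥ 1 population, recurrent sites (≥ 2
populations), and flagged sites (`|S| > 5`, strict); percentages are
nearest-integer, flagged relative to recurrent sites and the others
relative to tested sites.

**Association.** Pooled libraries get diploid-style calls from the
alternative-depth fraction: below 0.1 hom-ref, above 0.9 hom-alt,
otherwise het (band bounds inclusive on the het side); zero depth is
missing. Sites need a mean depth ≥ 10 across samples. Per site, ordinary
least squares regresses the paired phenotype — the mean embryo length of
the *following* generation, through an explicit generation-pairing map —
on the calls: with two genotype classes, the additive-dosage slope and
its two-sided t-test; with three classes, both the additive and the
categorical (two-contrast) codings are fitted and the smaller coefficient
p-value is reported, recording which coding produced it (the choice of
the two codings is controllable by a flag, since "a linear model" with a
smaller-p rule admits more than one reading). At least 3 complete samples
and 2 genotype classes are required; association p-values are reference
material for prioritization and are deliberately not multiplicity-
corrected.

**Embryo statistics.** Rank-sum tests enumerate the exact null while
`C(n+m, n) ≤ 10,000` and the pooled sample is tie-free, switching to the
tie-corrected normal approximation (no continuity correction) beyond
that: exactness where the small embryo samples live, tractability
elsewhere. Stripe tests are per stripe with BH adjustment across the
seven stripes. Intensity profiles are peak-normalized (max = 1) and
re-expressed relative to the posterior end so traces of different lengths
align at 0; comparisons interpolate linearly onto a shared 1 µm grid over
the traces' overlap. Replicated nuclei counts are averaged per embryo
before group summaries (mean ± SE). Viability is the per-replicate
eclosion proportion summarized as mean ± SE over replicates
(single-replicate groups report no SE), and proportion contrasts share
the Fisher kernel above.

## Validation experiments and their design

`evoreseq.validation` holds the seeded experiments the acceptance checks
and `scripts/acceptance.py` run. Problem sizes were chosen so the battery
finishes in a few minutes on one CPU while leaving comfortable
statistical margins.

- **EMS-rate recovery**: 20 mutagenized flies, 20 Mb, injected 3.0/Mb,
  deep uniform coverage (30×), 500 intermediate-frequency standing sites
  as background. Poisson counting error on the mean is ~3% (SE
  `sqrt(60)/20Mb/sqrt(20)`), far inside the 15% recovery band; standing
  singletons contribute < 1% at `Beta(2, 2)`.
- **Neutral sign-score scan**: 18 populations, 20,000 sites, all `s = 0`,
  the study's shallow coverage (29×, φ = 1). Drift between generations 3
  and 7 at `N = 300` moves frequencies by ~0.04 SD, invisible to Fisher
  tests at 29× after per-population FDR, so recurrent sites are rare and
  `|S| > 5` essentially never occurs.
- **Selection scan**: 10 standing sites at founder frequency 0.4–0.6 get
  `s = 0.25` in all 18 populations. Four generations of that selection
  multiply the allele odds by `1.25⁴ ≈ 2.4` (e.g. 0.5 → 0.71) — a shift
  whose per-population Fisher p at 29× is only ~0.1, invisible after FDR;
  the shallow regime is what the neutral control exercises. The
  validation therefore sequences these pools deep (mean 300, φ = 0.2),
  where the same shift yields z ≈ 4.8 and survives per-population BH,
  while neutral drift (z ≈ 0.9 at that depth) stays quiet; selected
  sites are compared against the 99th percentile of the neutral |S|
  distribution from the same run.
- **Association recovery**: one site with a 12 µm/copy length effect
  among 500 neutral sites, 18 populations. The three-class pooled call
  carries contrast only when pools sit near fixation or loss — every
  frequency inside the 0.1–0.9 band collapses onto "het" — so the
  experiment models bottle transfers with a small effective size (5
  diploids; the hom↔het transitions visible in real generation-paired
  pool data imply effective sizes far below census) and genotypes
  generation 15, by which most pools have absorbed. One sample per
  population keeps the 18 OLS observations independent: sampling the
  same drifting lineage twice correlates both genotype and phenotype
  across rows and inflates the neutral minimum p by orders of magnitude.
  The phenotype is the mean of 100 generation-16 embryo lengths
  (SE ≈ 1.5 µm against a 24 µm between-homozygote contrast).
- **Stripe-shift power**: cohorts of 60 vs 217 embryos (the published
  sample sizes) at baselines 550 vs 567 µm; the length coupling converts
  the 17 µm size change into a ~1.1 %EL anterior stripe shift, detected
  per replicate at q < 0.01.

## What the generator does not emulate

Passing these experiments shows the estimators are correct under the
generator's own assumptions, not that real data meet those assumptions.
The generator omits: linkage and haplotype structure during evolution
(sites drift independently), recombination, recurrent and back mutation,
sequencing and mapping error, reference bias, batch effects between
sequencing runs, indels and multiallelic sites (parsed and flagged on
input but never generated), selection acting on the phenotype itself
(fitness is per-site and constant, not mediated by embryo size), overlap
between generations, and any spatial realism in embryo measurements
beyond monotone stripe ordering and jittered nuclei spacing.

## Known limitations

- The recurrence scan treats populations as independent; replicate
  populations seeded from the same mutant pool share founders in the
  real design, which inflates apparent recurrence there.
- Sign-score significance is not calibrated analytically; the neutral
  percentile comparison is empirical by design.
- The association module inherits the low power of coarse pooled
  genotype calls at shallow depth; it ranks candidates, it does not map
  them.
- `covered_megabases` assumes the caller's depth band equals the
  filter's; supplying externally computed covered bases is preferred.
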
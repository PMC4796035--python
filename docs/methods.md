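# Methods

## The tests

**Trio scoring.**  A trio is a father-mother-offspring unit at one
bi-allelic marker; genotypes are alternate-allele dosages (0/1/2 diploid,
0/1 for hemizygous X males).  Conditional on the parents, the offspring
genotype has the Mendelian transmission distribution: each diploid parent
transmits one of its two alleles with probability 1/2; an X-chromosome son
receives only the maternal transmission; an X-chromosome daughter receives
the father's single allele with certainty plus a maternal transmission.
The model coding X is the dosage (additive), carrier status (dominant) or
alternate-homozygote status (recessive — except that a hemizygous male
expresses a recessive allele with one copy, so X-male recessive coding is
the dosage).  The trio score is (X − E[X], Var(X)) under that
distribution; Var(X) = 0 marks a non-informative trio (both parents
homozygous, or the matings whose possible offspring all code identically:
het × alt-hom under dominance, het × ref-hom under recessivity).

**FBAT.**  With coded trait T = Y − μ, the statistic is
U = Σ T(X − E[X]), Var(U) = Σ T² Var(X), Z = U/√Var(U), two-sided normal
p-values.  μ = 0.5 (the default) gives affected and unaffected offspring
equal and opposite weight; μ = 0 uses affected trios only.  Nuclear
families with several offspring contribute one trio per offspring, treated
independently (no between-sibling covariance correction).  Markers with
Var(U) = 0 are reported as undefined rather than given a fabricated
p-value, and are excluded from FDR ranking.  Mendelian-inconsistent
complete trios are excluded and counted, never summed into U.

**CIFBAT.**  Incomplete trios are expanded into their set of
Mendelian-consistent completions — distinct genotype configurations,
weighted uniformly.  (Uniform-over-configurations rather than weighting by
transmission multiplicity; the two differ only for patterns with a missing
parent, and the uniform reading matches "all valid completions equally
likely".)  Non-informative completions are kept and contribute (0, 0).
Each iteration draws one completion per incomplete trio independently,
adds U_m,r and Var(U_m,r) to the complete-trio totals and records
Z_r (Z_r := 0 when the total variance is 0, keeping the quantile sample
size fixed).  The interval is the empirical (α/2, 1−α/2) quantile pair of
{Z_r} with linear interpolation between order statistics; the interval
median is also reported but plays no role in the significance rule.  An
interval is significant at a p-value threshold iff both endpoints lie on
the same side of zero and both endpoint p-values clear the threshold — a
sign-straddling interval contains Z = 0 (p = 1) and can never be
significant.  With zero incomplete trios the sampler is skipped entirely
and the interval is degenerate at the FBAT Z, making CIFBAT a strict
generalization.  Reproducibility: one seed determines everything; marker
scans derive a per-marker substream from (seed, marker index) so results
do not depend on evaluation order or parallel scheduling.

**TDT and robustTDT.**  b and c count transmissions of the alternate and
reference allele from heterozygous parents to affected offspring;
χ² = (b−c)²/(b+c) with 1 df.  A transmission is counted only when it is
model-informative: the two candidate transmitted alleles would produce
different coded offspring genotypes given the other parent's realized
transmission.  Under the additive model this reduces to the classical
count (the ambiguous het × het → het trio contributes b+1 and c+1); under
dominance/recessivity it reproduces the non-informative mating types
above.  On the X chromosome fathers are hemizygous — never heterozygous —
so sons count only maternal transmissions and daughters count maternal
transmissions subject to informativeness given the paternal allele.
robustTDT computes, per incomplete affected trio, the set of (Δb, Δc)
increments over its completions, then takes exact min/max of χ² over the
reachable set of totals by dynamic programming on (b, c) pairs.  Interval
arithmetic on b and c separately would be loose because χ² is not jointly
monotone; the reachable set is O(n²) and exact.  Totals with b + c = 0
carry no evidence and enter the bounds as χ² = 0.  Note that adding an
incomplete trio need not widen the bounds: a trio whose every completion
forces a transmission (e.g. father missing, het mother, het offspring)
shifts both ends.

## The simulator

The generator emulates a two-subpopulation nuclear-family cohort at
independent bi-allelic autosomal markers.  Defaults (all configurable in
`SimConfig`): 4000 families split 1/3 : 2/3 between the subpopulations;
300 markers, 3 causative; 1 or 2 offspring per family (uniform), uniform
offspring sex; marker base frequencies Gamma(shape 2, scale 2)/35
(mean ≈ 0.114) clipped to [0.001, 0.5]; per-subpopulation frequencies by a
Balding-Nichols Beta perturbation at F_ST = 0.01 (the differentiation is
deliberately mild — enough to make "population" a meaningful missingness
target, not enough to stress the tests, whose conditioning removes
stratification effects anyway); Hardy-Weinberg parents; Mendelian
offspring.

**Disease model.**  log π_ij = α_ij + Σ_m β_m X(G_ijm) over the causative
markers, with per-family penetrance draws f2 ~ N(0.1, 0.01) and
f0 ~ N(0.001, 0.001) (second parameter is an sd; draws floored at 1e-5),
β(two copies) = log(f2/f0) and β(one copy) = half of it — the log-additive
midpoint, which is what "additive model" means on the log scale.  π is
clipped to [0, 1] and clips are counted.  α_ij = log f0 plus a
family-shared environmental term: with probability p_env the family is
exposed and its log-baseline rises by log(λ_s · f2/f0), i.e. an exposed
family's baseline risk is λ_s times the two-copy penetrance (λ_s = 3 by
default).  Siblings share the exposure and their parents' genotypes, which
is the source of within-family phenotype correlation; families are
independent.  λ_g = 2 is carried in the configuration for completeness but
the additive β coding is already fully determined by f0 and f2.

The environmental construction deserves a note, because it was a genuinely
open design choice.  The exposure magnitude must be large enough that a
realistic exposure probability can reach a double-digit population
prevalence — with f0 ≈ 0.001, a bare λ_s-fold baseline increase caps mean
prevalence below half a percent, making any calibration impossible.  Tying
the exposed baseline to λ_s · f2 (≈ 0.3) makes the target reachable, and
the π-clipping the model itself prescribes then saturates exposed
carriers, preserving a genetically enriched case pool — the regime in which
family-based tests have the power levels this kind of study reports.
`calibrate_prevalence` then bisects on p_env: a bank of probe replicates
(causative markers only) is simulated once with frozen exposure and
disease uniforms, making mean prevalence an exactly non-decreasing
deterministic function of p_env, so bisection converges cleanly through
the Monte-Carlo layer.  Cross-cohort prevalence is highly variable
(sd ≈ 4–5 percentage points at 4000 families, driven by the causative
frequency and penetrance draws), so both calibration and verification use
hundreds of probe replicates; with 600 each, the calibrated simulator's
measured mean prevalence lands within ~0.2 points of the 12.5% target.

**Missingness.**  A scenario is (mechanism, target, rate, split): MCAR
blanks uniformly chosen (individual, marker) entries of the selected
case/control trios at the given rate per marker; MAR/MNAR place an 80/20
split of those entries inside/outside a target group — subpopulation or
sex (evaluated on all trio members), disease status, or the genotype value
at the marker (heterozygotes / alternate homozygotes, the MNAR cases).
Disease status is a property of the phenotyped offspring only, so
case/control targeting distributes all of its missingness over offspring
entries (80% one status, 20% the other) and never touches parents.  This
matters: completions of an offspring-missing trio are symmetric (zero mean
under the additive coding), whereas uniform completions of a *parent*
-missing trio are biased toward carrier parents at low allele frequencies;
targeting whole case trios would therefore shift every null marker's Z_r
interval by several standard deviations and flood the interval rule with
false calls — behaviour that contradicts the precision this design is
known to deliver.  Mechanisms that hit cases and controls symmetrically
(MCAR, sex, subpopulation, genotype) may include parents because the
opposite-signed trait weights cancel the completion bias.  Infeasible
group sizes spill to the complement and are counted, never silent.

**Evaluation.**  Per run: simulate, assign disease (or a fair-coin null
phenotype), select all affected-offspring trios as cases plus an equal
number of unaffected-offspring trios as controls (the null harness trims
both sides to the smaller count instead of failing), inject missingness,
run FBAT and CIFBAT (100 completion iterations per marker in the study
configuration) across markers, apply Benjamini-Hochberg at FDR 10% to the
FBAT p-values, and transfer the BH step-up p-threshold to the CIFBAT
interval rule — CIFBAT never computes its own FDR.  Metrics against the
known causative set: recall, precision, specificity, NPV, F.  Aggregating
over runs, precision averages over runs that made at least one call (a run
that abstains has no precision; counting it as zero would conflate "no
calls" with "wrong calls"), and the cell F-measure is the harmonic mean of
the aggregated recall and precision, matching how such results tables are
conventionally assembled.

## Numerical and interface choices

* Genotype matrices are int8 with −1 for missing; the marker-scan fast
  path uses precomputed 3×3×3 score/consistency lookup tables and packed
  per-pattern completion-score tables (≤ 64 patterns per context), and is
  tested to reproduce the per-trio model objects bit-for-bit.
* Empirical quantiles use numpy's linear interpolation between order
  statistics; ties follow that rule.
* P-values below machine epsilon (2.22e-16) are floored to "<2.22e-16" in
  formatted output; in-memory values stay as computed.
* PED reading orients dosage against declared ref/alt alleles when the MAP
  carries the 6-column extension; otherwise the first allele observed at a
  marker becomes the reference and the orientation is recorded.  Offspring
  with unknown phenotype are excluded from trio construction and counted.
  A parent that is named but has no record contributes a missing genotype.
* The compact format is a transposed text matrix (one character per
  genotype, '.' missing) with the six PED columns as a '#'-prefixed
  header; it is diff-able, loss-free on dosages, and at most half the PED
  size by construction (1 byte per genotype vs ≥ 4).  Coordinates are
  1-based, as in MAP.
* Fully-missing trios are admissible for completion (15 autosomal
  configurations); callers who want to drop heavily missing trios can
  filter upstream.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run the study at its native
cohort size (4000 families, 300 markers, 3 causative, 100 CIFBAT trials)
and scale the *replicate* axis instead: 100 null runs at 500 families for
the null-calibration checks, 30 null runs and 50–60 disease runs at 4000
families, 16 runs per cell of the 9 × 4 scenario grid, and 600 probe
replicates for prevalence calibration/measurement.  Per-marker power is
what it is at a given cohort size, so shrinking families would make the
FDR procedure call nothing and render the recall/precision comparison
vacuous; shrinking replicates only widens Monte-Carlo error, which the
reported n makes explicit.

## What passing tests do and do not show

The simulator draws independent markers (no linkage disequilibrium), exact
nuclear families, error-free genotypes, and a dichotomous phenotype; real
cohorts violate all four.  Missingness mechanisms are single-variable
caricatures of real call-rate structure.  The disease-model environmental
construction is calibrated to a printed prevalence, not derived from a
stated formula, so simulation metrics that depend on the genetic fraction
of cases (notably FBAT's recall under case-concentrated missingness)
reflect this package's mapping rather than a universal constant; the
direction and ordering of the FBAT/CIFBAT comparisons are the robust
conclusions.  Null-calibration results (uniform p-values, interval
coverage shrinking with missingness, zero BH-level calls) are
construction-independent and transfer as stated.
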
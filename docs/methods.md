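# Methods

## Problem and model

`pollenflow` quantifies how the pollen received by mother plants differs
genetically across a hierarchy of spatial levels: mothers nested within
sites. For each seed it infers the haploid paternal (pollen) gamete by
subtracting the mother's genotypic contribution — the two-generation
("TwoGener") approach — and then partitions the variation among inferred
gametes with a nested analysis of molecular variance (AMOVA).

The estimands are the Φ-statistics

- Φ_CT = σ²_a / (σ²_a + σ²_b + σ²_c): differentiation of pollen pools
  among sites,
- Φ_SC = σ²_b / (σ²_b + σ²_c): differentiation among mothers within
  sites,
- Φ_ST = (σ²_a + σ²_b) / total: mothers across sites,

where σ²_a, σ²_b, σ²_c are among-site, among-mother-within-site, and
within-mother variance components. Reports additionally give the
*additive* decomposition Φ_SC + Φ_CT and the fractions
Φ_SC/(Φ_SC + Φ_CT), Φ_CT/(Φ_SC + Φ_CT), the conventional way of saying
how much of the total mother-to-mother differentiation is generated
locally versus between sites. Both conventions are computed and reported
separately because they differ whenever σ²_a and σ²_b are both nonzero.

## Gamete inference

At one locus, with mother genotype M and seed genotype O:

1. O homozygous (a,a): paternal allele is a (*unambiguous*);
2. exactly one allele of O absent from M: that allele is paternal
   (*unambiguous*);
3. O = M = (a,b), mother heterozygous: either allele may be paternal;
   the posterior over the two maternal-transmission hypotheses (prior ½
   each), weighted by pollen-pool allele frequencies p, is
   P(paternal = a) = p_a / (p_a + p_b) (*resolved*);
4. no allele of O occurs in M: *mismatch* (genotyping error or
   mis-assigned maternity); the locus is recorded as missing and
   counted, the seed is kept (a strict mode dropping such seeds is a
   one-line filter on the status table).

Pollen-pool frequencies for step 3 are estimated in a first pass from
unambiguous assignments only; a locus with no unambiguous assignment
falls back to uniform frequencies and is flagged. Optional EM-style
refinement passes re-estimate frequencies from all assignments; default
off — one refinement changed third-decimal digits of Φ in our
simulations and complicates reasoning about exchangeability.

**Reference pool.** The frequencies used for resolution are estimated
*per site* by default (`reference="site"`, falling back to the overall
pool at site/locus combinations without unambiguous data), with the
overall pool available as an option. The classical description of the
subtraction step uses the overall pollen pool, but that choice is not
innocuous: when pollen pools genuinely differ among sites, the global
ratio p_a/(p_a + p_b) is misspecified within each site, ambiguous
assignments are biased in a direction that depends on the mother's
genotype, and seeds of the same mother become artificially similar. In
null simulations (F_SC = 0) with among-site differentiation F_CT = 0.05
the within-site permutation test rejected at 0.136 instead of 0.05
under the overall reference; with the site reference the measured rates
were 0.028 (F_CT = 0) and 0.048 (F_CT = 0.05). Feeding the generator's
true gametes through the same test gave nominal rates, isolating the
inference reference — not the permutation machinery — as the cause.
Under the null of no within-site differentiation the site pool *is*
each mother's pollen pool, so the site-level reference makes the sampled
allele reproduce the correct conditional law and restores
exchangeability.

The mirror image holds one level up: the among-site test permutes whole
mothers among sites, and resolution against (noisily estimated)
site-level frequencies couples the seeds of a site, inflating Φ_CT's
null rejection rate (measured 0.24 at α = 0.05 on a small null design).
The rule is that a permutation test is valid when the resolution
reference is invariant under its own permutation stratum. The pipeline
and the simulation harness therefore evaluate the within-site test on
site-referenced haplotypes and the among-site test on
overall-referenced haplotypes; reported Φ estimates come from the
configured reference (site by default). Both null rates then sit inside
the binomial band around the nominal level (test suite, 300 null
replicates; acceptance run, 500).

**Resolution policy.** Ambiguous loci are resolved by *sampling* from
the posterior (default) or by MAP assignment. The default matters: MAP
gives every ambiguous seed of a given heterozygous mother the same
paternal allele, which manufactures within-mother similarity. In null
simulations (no true differentiation) the within-site permutation test
then rejected at rates of 0.50 (high diversity) to 0.95 (low diversity)
at α = 0.05 instead of 0.05. Sampling from the posterior reproduces the
correct conditional law of the paternal allele given the observed
mother–seed pair, restoring exchangeability: measured null rejection
rates were 0.03–0.07. MAP remains available for per-seed lookups where a
single best guess is wanted, and is deliberately not used anywhere in
the testing pipeline. Sampling is bit-reproducible given the run's RNG
seed, which every entry point requires or derives from a master seed.

## Distances and AMOVA

The squared distance between two haploid multilocus gametes is the
number of loci at which they carry different alleles (0/1 per locus).
Any positive per-locus weight would cancel in Φ, so the unit coding is
used. Loci missing in either gamete contribute 0 by default (preserves
metric additivity across loci); an optional mode rescales by the shared-
locus fraction. A pair sharing zero loci yields a flagged NaN distance
in the pairwise API and contributes 0 in the matrix path.

SSDs are computed from pairwise distances (SSD_total = Σ_{i<j} d²/N,
within-group analogues per mother and per site); this equals the
centroid-based nested ANOVA on one-hot allele indicators (Gower
identity), which the test suite uses as an independent oracle. The
unbalanced-design coefficients n′, n″, n‴ follow the standard
method-of-moments construction; components are obtained by equating
observed and expected mean squares. Negative component estimates are
reported as-is and flagged, never truncated to zero — small negative
values are the expected signature of no differentiation, and truncation
would bias the permutation null.

Degenerate designs (fewer than two sites, no replication of mothers
within sites, n′ or n‴ ≤ 0) raise a specific error naming the stratum.
Zero total variance flags the result and leaves Φ undefined (NaN).

## Permutation tests

- Φ_SC: seed-to-mother assignments are permuted independently within
  each site (per-mother counts and site memberships preserved). Only the
  within-mother SSD changes under this scheme, so the permutation
  distribution is computed from that single term, vectorized over
  permutations.
- Φ_CT: whole mothers, carrying their seeds, are permuted among sites
  (mothers-per-site counts preserved). Site totals and the design
  coefficients are recomputed per permutation from mother-level block
  sums of the distance matrix.

Both tests use the add-one convention p = (#{Φ_perm ≥ Φ_obs} + 1)/(n+1),
valid under exchangeability; default n = 999 permutations (199 in the
simulation experiments, where the Monte-Carlo replication dominates the
error). Sites with a single mother contribute no freedom to the
within-site test and are logged. Equality of the vectorized permutation
statistics with direct AMOVA recomputation under the same relabeling is
asserted in the test suite.

## Paternity-adjacent statistics

Probability of identity per locus: Σ p_i⁴ + Σ_{i<j} (2 p_i p_j)²;
multilocus product. Exclusion probability per locus: the probability
that a random individual carries no allele compatible with the
offspring's possible paternal alleles given the known mother, with
mother and offspring drawn under HWE and Mendelian segregation; the
implementation enumerates (mother, transmitted, paternal) combinations
and collapses the candidate analytically as (1 − Σ_{a∈T} p_a)²; the test
suite checks it against a full four-way enumeration to 1e-12.
Multilocus: 1 − Π(1 − P_E,ℓ).

Selfing classification replaces full-likelihood sibship reconstruction
with a deterministic two-step: (i) compatibility — the seed must be
producible from two maternal gametes at every doubly-typed locus, else
it is outcrossed; (ii) a multilocus likelihood ratio
P(seed | selfing)/P(seed | maternal gamete × pollen pool) converted to a
posterior under a configurable prior selfing rate (default 0.10) and
thresholded at 0.90 symmetrically (selfed / outcrossed / ambiguous).
This keeps the inferential goal — flagging selfed seeds before the
independent-pollination analysis — while being closed-form and exactly
testable; agreement with full sibship software on real data is not
claimed. With 11 loci of ≥5 alleles the classifier's recall of truly
selfed seeds exceeds 0.9 in simulation.

Model datasets: A = drop seeds called selfed, then one random seed per
fruit; B = one random seed per fruit; C = all seeds. The drop-then-
sample order in A matches the description "outcrossed offspring and a
single randomly chosen seed per fruit"; fruits emptied by the selfing
filter are dropped and logged. Sampling is seeded and reproducible.

## Synthetic data

The generator states a world with the hierarchical structure the
analysis assumes, not a fitted model of any particular landscape:

- per locus, global allele frequencies ~ symmetric Dirichlet(1);
  allele counts per locus drawn uniformly from 10–17 ("high" diversity,
  default, matching microsatellite batteries of 4–17 alleles skewed
  high) or 4–6 ("low");
- site pollen pools ~ Dirichlet around the global pool with
  concentration parent·(1−F_CT)/F_CT (Balding–Nichols construction:
  subpool fixation index has expectation F_CT, verified by moment
  simulation); mother pollen pools likewise around their site pool with
  F_SC;
- mother genotypes drawn in HWE proportions from site-level frequencies
  (gives mild adult structure, of the order of the F_ST ≈ 0.02 reported
  for comparable adult populations, without an extra parameter);
- seeds: maternal gamete from the mother plus a paternal gamete from
  the mother's pollen pool; with probability
  `fruit_paternity_correlation` all seeds of a fruit share one paternal
  draw; with probability `selfing_rate` the paternal gamete is instead a
  second maternal gamete.

Defaults emulate the motivating study design: 18 sites × 4 mothers × 5
fruits × 2 seeds (720 seeds), 11 loci. The preset grid crosses
diversity {high, low} × F_CT {0, 0.01, 0.05} × F_SC {0, 0.01, 0.08};
the nonzero levels bracket the empirically observed Φ range
(≈0.03–0.09). A `study_scenario` preset adds 10% selfing, 50%
within-fruit shared paternity, F_CT = 0.03, F_SC = 0.08.

What the generator does *not* emulate: spatial positions, pollinator
movement, genotyping error, null alleles, or missing data. A green
simulation test therefore establishes the statistical machinery under
Mendelian, error-free typing — not robustness to laboratory artifacts.

All randomness flows from a single scenario seed through spawned
`numpy` seed sequences (separate streams for frequencies, mother
genotypes, and mating), so regenerating one component does not shift
the others.

## Simulation experiments

`estimate_rejection_rates` runs replicates of simulate → infer → AMOVA →
stratified tests and reports rejection fractions with the 95% binomial
band around the nominal α (normal approximation p ± z·sqrt(p(1−p)/n),
the convention that yields (0.03, 0.07) for p = 0.05, n = 500;
Clopper–Pearson available). Default experiment sizes, 500 replicates for
type-I error and 200 for power at 199 permutations, fit single-CPU desk
hardware in minutes.

## Numerical and policy choices

- p-values: add-one convention; never zero.
- Missing-data rule: a half-called locus (one allele missing) is treated
  as fully missing for that individual — half-calls in fragment data are
  unreliable, and the mother-side policy is not standardized in the
  literature we follow; the rule is applied uniformly to mothers and
  seeds.
- Allele labels are opaque strings; fragment sizes are never interpreted
  numerically.
- MAP ties (posterior exactly 0.5) break to the lexicographically
  smaller allele label, deterministically.
- Zero pollen frequency for both alleles of an ambiguous pair: uniform
  resolution, weight 0.5, flagged.
- Thresholds: selfing posterior 0.90 (symmetric); prior selfing 0.10;
  all configurable.

## Known limitations

- The within-site type-I error is nominal, but the among-site test
  inherits the known inflation when within-site differentiation is
  present and mothers-per-site is small; the package reports both tests
  and leaves the design caveat to the user.
- No genotyping-error model in the paternity likelihoods; mismatch loci
  are dropped rather than error-corrected.
- Φ-statistics are reported for differentiation testing only; no
  effective-father counts or pollination-distance parameters are
  derived from them.
- The exclusion/likelihood selfing classifier is not a sibship
  reconstruction; seeds with few informative loci land in the
  "ambiguous" class rather than receiving a forced call.
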
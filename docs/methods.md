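# Methods

## The incompatibility fitness model

Two populations, north and south, each fixed for its own maternally
inherited mtDNA and (in the baseline model) homozygous at every one of n
nuclear loci for the allele coadapted with that mtDNA.  Per-locus fitness
against a given mitochondrial background: matched homozygote 1,
heterozygote 1 − s₁, mismatched homozygote 1 − s₂.  Mito-nuclear
interactions are assumed independent, nuclear loci unlinked, so organismal
fitness is the product of per-locus fitness values and the expected
fitness of any cross with exchangeable loci is a per-locus factor raised
to the nth power.

For each cross the per-locus genotype distribution follows from Mendelian
segregation: F1 is heterozygous everywhere (factor 1 − s₁); an F2 locus
unites two independent F1 gametes (¼ matched hom, ½ het, ¼ mismatched
hom); a maternal backcross (also any F1-male backcross) unites an F1
gamete with a matched parental gamete, so mismatched homozygotes are
impossible (factor 1 − s₁/2); a paternal backcross of an F1 female unites
an F1 gamete with a mismatched parental gamete, so fully matched
homozygotes are impossible (factor (1 − s₁)/2 + (1 − s₂)/2).  The literal
multinomial/binomial sums over locus-state counts are implemented
alongside the factorized forms as an internal cross-check; the factorized
form is the default because it is exact and O(1) per cross.  The
coefficients of the literal sums use Python's exact integer `math.comb`,
so they are stable at any n.

Ordering: W₃ ≥ W₁ and W₂ ≥ W₄ hold unconditionally; W₁ ≥ W₂ exactly when
s₂ ≥ 2·s₁ (per-locus algebra: (1 − s₁) − [1 − s₁/2 − s₂/4] = s₂/4 − s₁/2).
The reference parameterization used in examples and plots is s₁ = 0.05
(heterozygotes nearly unaffected — one coadapted allele is always
present) and s₂ = 0.5 (mismatched homozygotes severely affected).

### Parameters

| parameter | meaning | range | default in examples |
|---|---|---|---|
| n | nuclear loci interacting with the mitochondria | ≥ 0 | varied 1–20 |
| s₁ | heterozygote cost per locus | [0, 1] | 0.05 |
| s₂ | mismatched-homozygote cost per locus | [0, 1] | 0.5 |

n = 0 returns fitness 1 for every cross (empty product).  No dominance
parameter is modelled; s₁ itself absorbs dominance between the two
alleles.

### Polymorphic pools

`polymorphic_fitness` relaxes fixation: each pool carries its locally
adapted allele at a stated frequency, parents are drawn under
Hardy–Weinberg, and gametes are propagated through the chosen cross
against the maternal mtDNA.  Because every distribution involved is
Bernoulli in the matched allele, the per-locus genotype distribution of
the offspring is a product of two gamete frequencies, computed in closed
form.  At fixation this reduces exactly to the four baseline formulas.
Polymorphism softens hybrid breakdown in the symmetric case (both pools
at the same local-adaptation frequency p): the F1 gamete frequency is
then exactly ½, so F2 fitness equals the fixed-population value and the
paternal backcross gains matched homozygotes.  With *asymmetric* pools
the effect can reverse — if one pool's adapted allele is rare, hybrid
genotypes contain more mismatched homozygotes than in the fixed case and
fitness drops below the baseline value.  The maternal population names
the zygote's mtDNA (`maternal="north"` by default); the south-mother case
is the same computation with the profiles swapped.

## Monte-Carlo cross simulator

An independent stochastic realization of the same generative process: per
replicate and locus, gametes are drawn (fair coin flips for F1-derived
gametes, deterministic for parental gametes from fixed populations),
per-locus fitness values are multiplied, and the mean ± standard error
over replicates is reported.  One `numpy.random.Generator` seeded per run
makes output bit-reproducible.  Default 100,000 replicates resolve
fitness differences of ~0.01 at better than 4 SE.  Constant replicate
sets (F1, or zero costs) report an SE of exactly zero.

## Association statistics

Chi-square: Pearson test of independence on the 2 × 3 (population ×
genotype class) table via `scipy.stats.chi2_contingency` with no
continuity correction; genotype classes empty in both populations are
dropped before expecteds, so df = (kept classes − 1).  These two choices
reproduce the published per-gene p-values from the published counts.

Fst: the Weir & Cockerham (1984) θ for two populations from genotype
class counts, using sample sizes, allele frequencies and observed
heterozygosities per population; θ = a/(a + b + c) is reported unclamped
(small negative estimates are legitimate for undifferentiated samples),
and is undefined — reported as missing, never coerced to zero — for loci
monomorphic in the pooled sample.  Multilocus θ is the ratio of summed
components Σaₗ / Σ(aₗ + bₗ + cₗ), the convention of standard Fst software.
Counts may be real-valued so that expected Hardy–Weinberg class counts
can be pushed through the estimator to obtain the θ implied by a pair of
generating frequencies.

Per-gene reporting: the gene-level p-value is the smallest per-variant p
(a convention; the variants within a gene here form a single haplotype),
Bonferroni-corrected as min(1, m·p) with m = 14 candidate genes by
default; per-locus sample sizes are the sums of genotype class counts.
Missing genotypes are excluded per locus; loci must be biallelic.

## The co-occurrence screen

A variant passes if present in ≥ `min_in` samples of one mtDNA group and
≤ `max_out` of the other, evaluated in both directions (defaults 4 and 1,
sized for ~5 samples per group).  "Present" means the sample's calls
contain at least one alternate allele; missing calls count as absent
(conservative).  The exact null pass probability for group-independent
presence is computed by inclusion–exclusion over independent binomial
group counts and is verified in tests against brute-force enumeration of
all 2¹⁰ presence patterns of the 5 + 5 design.  At the defaults a variant
cannot pass in both directions simultaneously.

## Covariation scores

OMES over the species ungapped in both columns: Σ (N_obs − N_exp)²/N over
observed residue pairs, N_exp = product of marginals / N.  ELSC: the
subset is the species carrying the modal residue of column A (ties broken
lexicographically); for each residue y of column B the ideally
proportional subset count m̂_y apportions the subset size by
largest-remainder rounding (ties by larger full count, then residue
order), and the score is −ln Π C(N_y, n_y)/C(N_y, m̂_y), clamped at zero
since the proportional composition maximizes the product up to integer
rounding.  Scores above 5 (OMES) and 20 (ELSC) are flagged as implying
coevolution.  Species gapped in either column of a pair are excluded from
that pair only; pairs with fewer than two valid species are rejected.

The conservation grade is an explicit simplification of phylogenetic
rate-based conservation indices: the raw score of a column is the KL
divergence of its residue distribution from uniform over the alphabet
observed in the alignment, and grades 1–9 are assigned by rank-binning
raw scores within the alignment (9 = most conserved; ≥ 7 flags "highest
functionality").  It captures compositional bias only — no tree, no
branch lengths, no rate model — so grades are comparable within one
alignment but not across alignments.

## Synthetic data

The generators produce every input the pipeline reads, with ground truth:

* **Genotypes** — Hardy–Weinberg draws within each population at stated
  allele frequencies (genotype = Binomial(2, 1 − freq) copies of
  allele 2), 35 samples per population by default to match the genotyped
  cohort; optional i.i.d. missingness.  HWE-within-population is the
  generating assumption; real cohorts may violate it (inbreeding,
  substructure), so estimator-recovery results speak to sampling noise,
  not to model misspecification.
* **Presence matrices** — 5 + 5 samples by default (the ten-transcriptome
  regime), planted variants realized with exact (n_in, n_out) patterns,
  background cells i.i.d. Bernoulli.  Real variant calls are correlated
  across variants and samples (shared coverage, linkage); the null here
  is deliberately the independent-presence null the screen's false-positive
  rate is defined against.
* **MSA pairs** — background columns draw a consensus residue per column
  and emit it with probability equal to the conservation parameter
  (uniform residue otherwise); planted pairs put a balanced two-state
  split in column A and copy it into column B through a random residue
  bijection with probability equal to the coupling.  Real alignments
  carry phylogenetic correlation between species, which inflates
  covariation scores; planted-pair rankings here validate the scorers,
  not their calibration on real data.

All generators take a mandatory seed and are bit-reproducible.

## Fixture and numerical notes

The shipped `table2_genotypes.tsv` expands the published per-population
genotype class counts of the nine nonsynonymous variants in the six
associated genes into per-sample rows; sample ids are synthetic and
ungenotyped samples are recorded as missing.  One published table is
internally inconsistent: the ACO1 north classes sum to 34 against a
stated sample of 35.  The counts are taken at face value, which yields
θ = 0.295 against the published rounded 0.29; all other published values
reproduce at their printed precision.  The published Bonferroni value for
ACAD9 (0.046200) equals 14 × the p-value *after* rounding to its printed
precision (0.0033); the unrounded pipeline value is 0.046305.

Acceptance-style checks use 100,000 Monte-Carlo replicates for the
fitness model, 10,000 null variants for the screen and 200 replicate
tables per regime for estimator recovery — sizes at which the statistical
tolerances (4 SE, 3 binomial SE, ±0.03) are comfortably resolved on a
single CPU in seconds.
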
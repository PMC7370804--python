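# Methods

## Exact-match strain demultiplexing

Strains of a single invading species are distinguished by strain-diagnostic
marker amplicons: each strain carries one or more expected PCR-product
sequences unique to it within the database.  A merged read is scored for a
marker iff the read — or its reverse complement — equals the marker exactly
(same length, 100 % identity).  The rule is deliberately strict: a single
substitution, or any `N`, disqualifies a read, which is counted unmatched.
Matching is therefore a dictionary lookup, orientation-symmetric by
construction, and reverse-complement acceptance can be disabled
(`allow_rc=False`) for libraries with fixed orientation.

Counts ("abundance") convert to relative shares, count/total-matched, over
a fixed label universe (the designed strains after group collapsing), so
undetected strains appear with share 0.  The share table at the invasion
day is the *DNA-amount baseline*; strain-specific invasion success is the
arithmetic difference of shares, Δshare = end − baseline, which sums to
zero over a mixture because both timepoints are compositional.  The
change-metric choice was genuinely open — the quantity is only described
as a "relative gain or loss" in this experimental tradition — and the
arithmetic difference is the simplest statistic with the zero-sum property;
a log-ratio variant can be built from the same share tables if needed.

Indistinguishability groups (strain pairs whose amplicons cannot be told
apart) are declared in the marker FASTA via `;group=` tags.  When at least
two group members are co-introduced, their counts are pooled under a
combined alphabetical label ("A and B"); a group with a single designed
member stays an individual strain.  Pooling preserves the total matched
count.  Mixtures in which any designed strain-or-group has baseline share
0 are excluded with a recorded reason, since their gain/loss cannot be
referenced to the inoculation.  Markers of strains whose primers were not
used in a sample's experiment may stay in the database; hits on them are
reported separately as a cross-contamination diagnostic.

No depth normalisation or rarefaction is applied: shares are
depth-invariant, and raw counts are retained for diagnostics.  No
correction for amplicon length or marker copy number is applied either;
the synthetic generator exposes a per-strain copy bias precisely so the
consequences of that simplification can be studied.

## Invasion yield and the diversity verdict

Observed yield is the invader's endpoint share of total community biomass
(a biomass variant is available via `yield_metric="biomass"`).  Under the
substitutive design the total inoculum is constant across richness levels,
so each of k strains enters at 1/k of it (0.1 μg ml⁻¹ total → 0.033 to
0.01 μg ml⁻¹ per strain for k = 3…10).  The null expectation for a
mixture is the unweighted mean of its component strains' monoculture mean
yields: each strain at 1/k inoculum contributes 1/k of its monoculture
yield if strains neither help nor hinder each other.  The invasion yield
is ln(observed/expected); zero observed yields (failed invasions) return a
−∞ sentinel and are excluded from level means with a logged count rather
than patched with a pseudo-count.

Per richness level the mean and a two-sided 95 % Student-t CI
(mean ± t₀.₉₇₅,ₙ₋₁ · s/√n) are computed; a positive diversity effect is
declared only when the mean is positive and the CI excludes zero.  The CI
method is a design choice — Student-t on replicates is the standard small-n
interval and its coverage is verified empirically (below).  Strain-level
variability is summarised by CV = sample SD / mean of community shares,
dominance counts (end share > 0.66 in a mixture), and the Spearman rank
consistency between monoculture yield and mean in-mixture share gain.
Spearman rho and its t-approximation p come from `scipy.stats.spearmanr`;
for n ≤ 8 the p-value is replaced by the exact enumeration over all n!
orderings.

## Biovolume and stoichiometry

Cell volume follows the standard geometric-solid conventions (sphere
πd³/6; cylinder π(d/2)²·L; prolate spheroid πd²L/6; ellipsoid πabc/6;
double cone πd²L/12), with per-species shape assignments supplied in the
census table, not hard-coded.  The census provides one mean dimension set
per species and sample; per-cell size distributions are out of scope.
Biomass is abundance × volume at unit density (1 g cm⁻³, the fresh-weight
convention), so 10⁶ cells ml⁻¹ of 1 μm³ equal 1 μg ml⁻¹.  Molar C:N:P
ratios divide elemental masses by atomic masses (C 12.011, N 14.007,
P 30.974); the Redfield constants 6.6 (C:N) and 106 (C:P) are exposed as
reference values.  Zero denominators yield flagged NaNs.

## PERMANOVA, distances, ordination

Bray–Curtis dissimilarity, d(x,y) = 1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ), is computed
with `scipy.spatial.distance.pdist`; all-zero samples are an error naming
the sample.  The one-way PERMANOVA is implemented directly from the
pseudo-F definition on squared distances:

    SS_total  = (1/n) Σ_{i<j} d²ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ij
    F = (SS_among/(a−1)) / (SS_within/(n−a)),   R² = SS_among/SS_total

with an unrestricted label-permutation null (the appropriate scheme for a
single factor with exchangeable samples) and the p-value estimator
(1 + #{F* ≥ F_obs}) / (1 + n_perm), which can never return 0.  For n ≤ 8
all n! permutations are enumerated and the p-value is the exact fraction
#{F* ≥ F_obs}/n! including the identity.  Permutation statistics are
rounded to 12 significant digits before the ≥ comparison so floating-point
noise cannot inflate or deflate the tie count; perfect separation
(SS_within = 0) is handled as F = ∞, which compares correctly against
permuted statistics.  An identically-zero distance matrix leaves F
undefined (degenerate result, flagged).  The strain-effect test restricts
to single-strain microcosms, drops the invader column, groups by strain
identity and additionally reports mean within-strain vs between-strain
distances.

PCA is covariance PCA (column-centred, unscaled) by SVD; signs are fixed
so each component's largest-magnitude loading is positive, and
scores·loadingsᵀ + column means reconstructs the input.  Down-stream runs
ordinate resident biomass as given; share-based ordination can be obtained
by normalising the community matrix first.

## Synthetic experiment generator

The generator emulates the statistical structure of an invader-addition
microcosm study, not any particular system's dynamics.  Its discrete-time
model is the minimal construction reproducing the qualitative regimes the
analysis must handle; per day, biomass of population i updates as

    B_i ← B_i · exp( r_i (1 − T/K) − a·G·s_i − δ )

with total biomass T, carrying capacity K = 12 μg ml⁻¹, attack rate
a = 1.6 (animals ml⁻¹)⁻¹ d⁻¹, grazer density G on a regime-specific
deterministic trajectory, susceptibility s_i scaled by regime preference
factors, and dilution δ = 0.1 d⁻¹ (the simple-interest reading of 20 %
medium exchange every second day; exposed as a parameter since other
conventions give slightly different rates).  Four grazer regimes:

* `none` — G = 0; the invader's growth advantage lets it exceed 50 % of
  community biomass by the end.
* `generalist_high` — G = 1.5 ml⁻¹, heavy grazing on the invader
  (preference 1.0) and light on residents (0.05): grazing mortality
  exceeds invader growth, invasion fails (consumptive resistance; endpoint
  invader share ≲ 10⁻⁶).
* `generalist_low` — G starts at 0.2 ml⁻¹ and collapses (−0.25 d⁻¹),
  mimicking consumer failure; invasion succeeds late.
* `specialist` — G = 1.0 ml⁻¹ grazing residents and invader weakly
  (0.05 / 0.25 × susceptibility): consumer and invader coexist and
  endpoint invader shares spread widely across strains.

Residents grow at 0.35 d⁻¹ with per-microcosm lognormal jitter
(CV 0.08) on rates and initial biomass — the only use of the seed in the
dynamics, providing replicate noise.  Strain traits plant the structure
the statistics must recover: growth rates evenly spaced over a 2× range
(0.5–1.0 d⁻¹) assigned to strain ids in seeded random order,
susceptibilities uniform in [0.4, 1], marker copy bias defaulting to 1 (a
knob for studying what share-based baselines do and do not correct).
The experimental design follows the substitutive convention: total invader
inoculum 0.1 μg ml⁻¹ (5 % of the 2 μg ml⁻¹ resident community), split
equally across strains at every richness level; single-strain treatments
replicate every strain of the pool so each has a monoculture yield.
Sampling days default to the invasion day (6) plus 8 and 32 days.

Reads are drawn multinomially with probabilities ∝ biomass × copy bias;
each read is the exact marker sequence, reverse-complemented with
probability 0.5 and corrupted by independent per-base substitutions at
rate ε (default 0, so demultiplexing loss is fully controllable).
Markers are seeded random 120-mers, unique across both orientations.
FASTQ is written with uniform Q40 qualities.

What the generator does **not** emulate: real marker databases (primer
cross-amplification, length variation), chimeras and PCR/sequencing
artefacts beyond iid substitutions, akinete formation or N-fixation
feedbacks, consumer-resource grazer dynamics, and wall effects.  Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the assumed sampling models, not robustness to every
failure mode of real amplicon data.

## Verification and problem sizes

The acceptance checks run at these sizes, chosen so the full suite
completes in well under a minute while keeping Monte-Carlo error small
relative to each tolerance: demultiplexer recovery over 20 seeded
datasets of 2–10 strains at depth 10⁴ (≥ 95 % of strain cells within 3
multinomial SD); PERMANOVA sampled-vs-exhaustive agreement at n_perm = 10⁵
on five n ≤ 8 instances (within 3 Monte-Carlo SE, plus the constructed
4-sample two-block instance whose exact p is 1/3); type-I error over 1,000
null communities at α = 0.05 (±0.02); invasion-yield CI coverage over
1,000 null datasets of n = 15, σ = 0.2 (95 % ± 2 %) and power ≥ 95 % for a
planted mean log-yield of 0.5; and positive strain-consistency rho in
≥ 95 % of 100 generator runs (each: 5 monocultures + all 10 three-strain
mixtures, depth 10⁴).

## Known limitations

* Exact matching is intentionally brittle to sequencing error; with ε > 0
  the matched fraction decays as (1−ε)^L and shares stay unbiased only
  because errors are strain-independent.  Real error profiles need not be.
* The substitutive-null expected yield uses the unweighted mean of
  monoculture yields; alternatives (max of components, partition-based
  null models) are deliberately not defaulted and would need their own
  calibration.
* PERMANOVA treats samples as exchangeable; nested or repeated-measures
  designs are out of scope.
* The generator's dynamics are phenomenological; its parameter values are
  generator choices, not estimates of any real community.
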
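# Methods

## Scope and data model

`admixscan` operates strictly downstream of local-ancestry inference. Its
raw input is a complete haplotype × SNP matrix of integer ancestry codes
(default three-way coding EUR→0, NAM→1, AFR→2) tied to a SNP map with
1-based physical positions and genetic positions in Morgans. Missing calls
are rejected, not imputed: post-QC local-ancestry matrices are complete,
and silently imputing ancestry would bias every downstream variance.
Two on-disk dialects are read and written — a TSV with one row per
haplotype, and a LAMP-LD-style layout with one digit string per individual,
two digits per SNP. The exact file layout of LAMP-LD output is not
standardized, so the dialect is always an explicit argument; the reader
never guesses. Sample sex is carried as metadata only and never enters a
computation (the pipeline addresses autosomes).

## Deviation scan

At SNP *i* the number of target-ancestry haplotypes among K sampled
haplotypes is modeled as Binomial(K, pᵢ); the null is pᵢ = p₀ with p₀ the
genome-wide mean. Binomial-MLE asymptotics give the default score
statistic z = (p̂ᵢ − p₀)/√(p₀(1−p₀)/K) with a standard-normal upper tail.
The field often calls this procedure a *t*-test; at K = 370 the score,
Wald (SE at p̂) and Student-t (K−1 df) versions agree to the order of
magnitude even at z ≈ 5 and essentially exactly for moderate deviations,
so all three are provided and the choice is a config flag, not a result.
Two numerical guards: p-values are clamped to the smallest positive
representable double so −log₁₀ transforms never overflow, and a Wald
request at p̂ ∈ {0,1} falls back to the score SE with a warning rather
than returning an infinite statistic.

p₀ defaults to `"auto"` — the realized genome-wide mean of the analysed
matrix — because that is how a real scan anchors its null to its own
sample; any fixed value (e.g. 0.52) can be supplied. The default tail is
`upper` (ancestry *excess*); deficit and two-sided scans are options.
No multiple-testing correction is applied beyond the fixed per-SNP
threshold (default 10⁻⁵): the genome-wide decision is explicitly delegated
to the neutral-replicate calibration below, which is the point of the
design. Significant SNPs can be grouped into regions with a configurable
inter-SNP gap (default 500 kb — a reporting convenience with no effect on
any statistic).

The score test tracks the exact Binomial(370, p₀) upper tail within a
factor of two for p̂ between 0.55 and 0.70 (asserted on the full integer
grid in the tests), and on i.i.d. null matrices its rejection rate matches
the attainable level of the discrete statistic within binomial noise; the
attainable level itself sits within one lattice step of the nominal α.

## Drift + sampling variance model and the Nₑ estimator

An ancestry proportion starting at p₀ and drifting neutrally for T
generations in a Wright–Fisher population of 2Nₑ haploid genomes has
variance p₀(1−p₀)(1−e^(−T/2Nₑ)) in the diffusion limit; the discrete
factor 1−(1−1/2Nₑ)^T differs by <10⁻⁴ relative for the regimes here
(T ≤ 20, Nₑ ≥ 500) and both are implemented, the diffusion form being the
default used everywhere. The distribution of the drifted proportion is
approximated by the moment-matched Beta; compounding with Binomial(K)
sampling of haplotypes gives

    var(k/K) = p₀(1−p₀)/K · (1 + (K−1)ρ),  ρ = 1 − e^(−T/2Nₑ),

verified in the tests against numeric quadrature of the compound (10⁻⁸
relative) and against Monte-Carlo Beta-then-binomial draws.

The estimator inverts this closed form at the empirical across-SNP
variance of the observed ancestry fraction: ρ̂ = (K·V/(p₀(1−p₀)) − 1)/(K−1),
Nₑ = −T/(2 ln(1−ρ̂)). T is always supplied, never jointly inferred. A
Brent-root fallback on the forward model is retained as an independent
cross-check (agreement 10⁻⁹ relative on a grid). The empirical variance
uses *all* SNPs, linked or not, with the population (1/M) denominator:
linkage does not bias the matching identity (the marginal per-SNP variance
is what the model describes) but it inflates the estimator's sampling
noise relative to the unlinked ideal, so single-dataset estimates from
dense maps should be read with that in mind. Domain guards: V at or below
the pure-sampling floor p₀(1−p₀)/K means no detectable drift (Nₑ → ∞,
raised as an error rather than returning infinity); V at or above
p₀(1−p₀) exceeds full fixation.

At 5,000 unlinked loci and K = 370 the estimator's Monte-Carlo sampling SD
is ≈7–8% of Nₑ (dominated by the chi-square noise of the across-locus
variance); recovery tests and the acceptance script use that scale.

## Forward simulator

State is tract-based: a haplotype is a list of (start, end, ancestry)
intervals in genetic units, junction-minimal, never a per-SNP vector, so a
population of 4,500 diploids over 15 generations is a desk-scale
computation. Internally all chromosomes are concatenated on one genetic
axis and a meiosis is realized as a set of switch points: a
Poisson(total Morgans) number of crossover positions drawn uniformly
(uniform positions restricted to within-chromosome spans are exactly
per-chromosome Poisson processes), plus an independent fair-coin switch at
each chromosome boundary, which is equivalent to independent assortment
with a per-chromosome random starting phase. No crossover interference and
no obligate crossover are imposed — a plain Poisson model per Morgan.
The per-chromosome tract view required by the public API is recovered by
slicing the flat representation at chromosome offsets.

Demography: a single pulse — generation 0 is 2Nₑ single-ancestry founder
haplotypes drawn i.i.d. from the admixture proportions; each later
generation resamples parents uniformly with replacement (hermaphrodite
default, selfing allowed; a `two_sex` mode draws mothers and fathers from
disjoint pools and is ancestry-neutral on autosomes); after T generations
`n_sample` diploids are drawn **without replacement**. Two consequences
are handled exactly in the validation tests rather than idealized away:
the i.i.d. founder draw adds one extra genome-wide resampling event (an
offset shared by all loci, hence absorbed whenever the scan uses the
replicate's own mean as p₀), and without-replacement sampling deflates the
binomial sampling term by the finite-population factor 1 − K/2Nₑ (≈4% of
that term at K=370, 2Nₑ=9,000). With those two corrections the simulator's
across-replicate per-SNP variance matches the analytic drift+sampling
model within Monte-Carlo error, and its junction density matches the
L·T·(1−Σαₖ²) expectation for T ≪ Nₑ.

SNP maps are projected onto simulated genomes by linear bp→Morgan scaling
per chromosome (no genetic map is assumed); tracts are half-open, a SNP
exactly at a junction takes the tract starting there, and a SNP at a
chromosome's very end takes the last tract. The default genome is 189
chromosomes of 0.2 M (total 37.8 M, close to the human autosomal map) with
SNP positions uniform over the physical genome; a literal 20 M per
chromosome is available via `chrom_morgans` for users who want a much
longer genome, but 0.2 M is the default because 189 × 20 M would total
~100× the human autosomal map length. Batch replicates derive child
streams from the master seed via `SeedSequence(entropy=seed,
spawn_key=(replicate,))`, so any single replicate is reproducible in
isolation and results are bit-identical for a fixed seed.

What the generator emulates: single-pulse three-way admixture, constant
Nₑ, uniform recombination, spatially autocorrelated local ancestry at the
sampled SNPs. What it does not: real genetic-map heterogeneity (hot/cold
spots), continuous or multi-pulse migration, selection of any kind,
local-ancestry caller error (calls are read off tracts perfectly), and
assortative mating. Passing tests therefore demonstrate correctness of
the neutral machinery, not robustness to caller noise or demographic
misspecification.

## Null calibration and its honest limits

Each neutral replicate is simulated, projected and scanned exactly as data
would be (p₀ from the replicate's own genome-wide mean); the SNP
maximizing the signed excess p̂ − p₀ is recorded with its p-value
(an absolute-deviation variant is a flag). The verdict logic: an observed
scan minimum is attributed to selection only if it lies below the
threshold, below every neutral extreme, and no neutral replicate itself
breached the threshold. `expected_min_p` (1−(1−x)ⁿ) gives the
independence baseline for sanity checks; linked SNPs reduce the effective
n.

A quantitative caveat that the replicate experiments expose: when Nₑ is
chosen to match the observed ancestry variance, the true per-SNP variance
exceeds the binomial variance the score test assumes by the factor
1+(K−1)ρ — about 1.41 at (K=370, T=10, Nₑ=4,500) — so neutral
max-deviation z-scores are ≈1.19× inflated relative to nominal, and with
~10²–10³ effectively independent ancestry blocks per genome a neutral
replicate produces a sub-10⁻⁵ SNP with probability of order 10–25% at
20,000 SNPs on a 37.8 M genome. Drift alone therefore *can* breach a fixed
10⁻⁵ threshold at these parameters, and the package's tests report this
behaviour rather than assume it away. The practical reading: the per-SNP
threshold is a screening device; the defensible genome-wide criterion is
the comparison of the observed extreme against the neutral replicate
distribution (`compare_to_threshold`), and observed peaks several orders
of magnitude below the neutral extremes (e.g. 2.4×10⁻⁷ against neutral
minima near 10⁻⁵–10⁻⁴) remain clearly attributable to selection.

## Problem sizes used by tests and the acceptance script

Nₑ-recovery runs use 5,000 unlinked loci per (T, Nₑ) setting; full
forward-simulation checks use 20,000 SNPs on the 189 × 0.2 M genome with
Nₑ = 4,500, T = 10 and 185 sampled diploids, with 5–20 replicates
depending on the check — sizes at which every quantity's Monte-Carlo error
is small relative to its test tolerance while a full run stays in the
minutes range on one CPU. All tolerances are stated in the tests
themselves (3–5 Monte-Carlo SEs for stochastic quantities; 10⁻⁶–10⁻¹²
relative for algebraic identities).
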
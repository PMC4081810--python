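# Methods

This note documents the models implemented in `popdiv`, the assumptions
behind them, the defaults and why they were chosen, the numerical
details that affect results, and what the synthetic-data calibrations do
and do not demonstrate.

## Sequence handling and site policies

Input alignments are pre-aligned FASTA, one file per locus, uppercased on
read; the description after the first whitespace is ignored and sample
ids are case-sensitive. Loci sharing a sample-id set are concatenated
with recorded boundaries, so per-site statistics are invariant to locus
order.

Two site policies handle gaps, `N` and IUPAC ambiguity codes:

- **complete deletion** (default): any column containing a non-ACGT
  symbol in *any* sample is removed once, before haplotype collapsing
  and all diversity statistics. This matches the default of the standard
  population-genetics packages and keeps every pairwise comparison on
  the same set of sites.
- **pairwise deletion**: each pair is compared on the sites where both
  members carry an unambiguous base; per-locus statistics rescale to the
  mean comparable length.

Haplotype identity is exact string equality after the site policy;
ambiguity codes are never expanded. Haplotypes are ordered by descending
total count, ties broken lexicographically, which makes all downstream
outputs (tables, networks, GraphML) deterministic.

## Diversity and differentiation

Gene diversity uses Nei's unbiased estimator
`h = n(1 − Σp_i²)/(n − 1)` with the Nei (1987) sampling variance;
nucleotide diversity is the mean per-site pairwise difference with the
total (stochastic + sampling) variance. Between-population divergence is
`d_xy` (mean per-site distance over all cross-population pairs) and the
net divergence `d_a = d_xy − (π_X + π_Y)/2`. Note two exact properties
used in the tests: `d_a ≤ d_xy` always, and `d_a` is only zero *in
expectation* for two independent samples of one population — literally
duplicating a sample yields `d_a = −π/4` because cross pairs include
identical individuals while π excludes self-pairs.

Distances: raw differences, p-distance, and Jukes–Cantor
`d = −(3/4)·ln(1 − (4/3)p)`, undefined at `p ≥ 3/4`.

### AMOVA

The two-level analysis of molecular variance follows the Excoffier
sums-of-squares decomposition, with the supplied model distances
entering directly as squared Euclidean distances — the convention of the
standard molecular-variance software, which treats the (possibly
model-corrected) pairwise difference matrix as δ². Variance components
come from equating mean squares to their expectations with the usual
unequal-sample-size coefficient `n' = (n − Σn_g²/n)/(g − 1)`;
Φ = σ²_a/(σ²_a + σ²_w). Significance permutes individual assignments
among the groups — the only exchangeable unit in a two-group,
one-population-per-group design — and uses the add-one estimator
`p = (1 + #{Φ* ≥ Φ})/(n_perm + 1)`, so `p ∈ [1/(n_perm+1), 1]` and no
p-value is ever exactly zero. For two groups the AMOVA Φ equals the
pairwise Φ_ST computed from the same matrix (tested as an identity).

### Neutrality statistics

Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂);
it is *undefined* — returned as NaN, never 0 — when S = 0, and also at
n = 3 where c₁ = c₂ = 0 collapses the variance.

Fu's Fs takes θ = θ_π (the mean number of pairwise differences), fixed
by definition and documented here. The probability
`S′ = P(K ≥ k_obs | θ, n)` comes from the Ewens sampling formula
`P(K=k) = |s(n,k)| θᵏ / θ^(n̄)` with unsigned Stirling numbers of the
first kind computed exactly as integers and only then mapped to log
space (bit-shifted logs for values beyond float range), so there is no
overflow for any realistic n. `Fs = ln[S′/(1 − S′)]`; undefined when
k = 1 or S′ degenerates to 0 or 1.

## Mismatch distributions and the sudden-expansion model

The mismatch distribution is the histogram of raw pairwise differences.
Under a sudden expansion (scaled size θ₀ → θ₁ at mutational time
τ = 2ut before present) the expected distribution has the exact
two-epoch form

    F_j = F̂_j(θ₁) · P[Γ(j+1) ≤ τ(1 + 1/θ₁)]
        + e^{−τ(1+1/θ₁)} · Σ_{i=0}^{j} (τ^i/i!) F̂_{j−i}(θ₀),

with `F̂_j(θ) = θ^j/(1+θ)^{j+1}` the stationary geometric distribution.
This is evaluated with regularized incomplete-gamma calls and a single
convolution; it sums to one to 1e-9 over the test grid and needs no
truncated infinite series. θ → 0 limits are handled as point masses at
j = 0.

The fit minimizes `SSD = Σ_j (obs_j − exp_j)²` over **normalized
frequencies** (not raw counts, so SSD is comparable across sample
sizes), by L-BFGS-B from a small moment-based multi-start
(the histogram mean estimates τ + θ₀ when θ₁ is large) followed by a
Nelder–Mead polish; bounds are τ ∈ [0, 4(j_max+1)], θ₀ ∈ [0, 100],
θ₁ ∈ [0, 5000]. On the model's own expected curve the fit returns τ
within 5% (tested). A histogram with all mass at zero returns the
boundary fit τ = θ₀ = 0 with a flag; θ₁ < θ₀ (a contraction) is allowed
but flagged.

The SSD p-value is a parametric bootstrap: coalescent samples are
simulated under the fitted expansion (same n and L), refit with the
same optimizer settings, and `p = (1 + #{SSD* ≥ SSD})/(n_boot + 1)`;
the expansion hypothesis is "not rejected" at p > 0.05. One seed drives
all replicate simulations.

## Demographic unit conversions

Generation time is the life-history identity `T = a + s/(1 − s)` (age at
maturity `a` in years, adult annual survival `s`); with a = 2.5 and
s = 0.35 this gives 3.04 years. It is strictly increasing in both
arguments.

Mutation-scaled IM parameters convert linearly: `t_years = B/U`, where U
is the per-locus per-year rate aggregated across loci — arithmetic mean
by default (matching the source analysis's use of mean rates), geometric
mean available since IM-style software conventionally uses it; the
aggregation used is recorded in the output. Sizes use
`N = q/(4·U·T·scalar)` with an inheritance scalar defaulting to 1 (no
ploidy correction — mtDNA-like loci are treated at face value, and the
simulator makes the same choice); `Nm = (q/4)·m`. The published
divergence-time conversion for the motivating data set is not exactly
reproducible from any simple mean of the stated per-locus rates, which
is why both aggregations are exposed and the conversion reports its
inputs.

## Statistical-parsimony networks

The connection limit is the largest number of mutational steps j whose
probability of being free of superimposed changes is at least α
(default 0.95). For sequences of length L differing at j sites, per-site
mutation counts are modelled as Poisson with mean λ(j), the Jukes–Cantor
divergence re-estimated from j (λ = −(3/4)ln(1 − 4j/3L)); a j-step
connection is parsimonious when each differing site carries exactly one
hit and each identical site none:

    P(j) = [λe^{−λ}/p(λ)]^j · [e^{−λ}/(1 − p(λ))]^{L−j},
    p(λ) = (3/4)(1 − e^{−4λ/3}).

P(0) = 1, P decreases in j, the limit grows with L and shrinks with α,
and α → 0 accepts everything — all tested. For the 1077-bp two-locus
fragment the 95% limit is 10 steps (5 at 350 bp, 8 at 727 bp), so a
four-step inter-population connection is comfortably admissible.

Network construction joins haplotype pairs in increasing mutational
distance (raw differences on complete-deletion sites); within a distance
class, ties break by higher frequency product then lexicographic node
id. A pair is connected only if its components were distinct when the
distance class opened: this retains all alternative equal-length
connections (loops) — the source figures do not document loop breaking,
so nothing is discarded — and never adds shortcuts. Multi-step edges are
expanded through inferred intermediates `mv1…mvK`, named in insertion
order, so every final edge is exactly one change. Star-shaped input
yields a star; output GraphML is byte-identical across runs.

## Background niche divergence test

Rasters are ESRI ASCII grids (cell-center registration, lon/lat WGS84,
nearest-cell extraction); rows with missing climate are dropped with a
logged count. Variable pruning is greedy in a caller-supplied priority
order (the "more temporally inclusive" criterion of the source analysis
is not operational, so priority is an explicit input): a variable is
kept only if |Pearson r| ≤ 0.80 against everything already kept.

Backgrounds are minimum convex polygons around each lineage's
occurrences, sampled uniformly by rejection (nodata excluded,
seed-reproducible, default 1000 points). The PCA is computed on the
**pooled backgrounds of both lineages** — the background-test design
asks what environmental space is *available*, so occurrences are
projected, not fit — and on the **correlation matrix** (z-scored
variables), because bioclimatic variables mix °C and mm; the sign of
each loading vector is fixed by making its largest-magnitude element
positive.

Per axis, the observed statistic is |mean_A − mean_B| of occurrence
scores; the null resamples ⌈0.75·n⌉ background rows per lineage
*without* replacement (the "75% replacement" of the source method is
read as a delete-25% jackknife; a with-replacement bootstrap is a
switch) and recomputes the background divergence 1000 times. Divergence
is declared when the observed difference exceeds the upper bound of the
middle-95% null interval, conservatism when it falls below the lower
bound, otherwise the axes are indistinguishable.

## Synthetic data

Sequence generators simulate coalescent genealogies with msprime (the
standard coalescent engine) and overlay finite-sites Jukes–Cantor
mutations on a discrete genome — finite sites, not infinite sites, so
simulated data exercise JC distances, multiple hits and haplotype
collapsing exactly as real data do. Loci are haploid with effective size
N (mtDNA-like; no ploidy scaling), consistent with the conversion
default above. Because the engine is the backend, simulator correctness
is checked against closed-form coalescent expectations rather than
against another run of the same engine: mean pairwise diversity matches
θ = 2NuL within Monte-Carlo error, a deep split with no migration gives
reciprocal monophyly and Φ near 1, and increasing 4Nm monotonically
erodes Φ.

The expansion generator maps (θ₀, θ₁, τ) to simulator units through an
arbitrary per-site rate (10⁻⁷/site/generation): only the products 2Nu
and 2ut matter, so the choice is inert; θ = 0 is clamped to 10⁻⁴ to keep
sizes positive.

The niche generator builds z-scored random fields (smoothed white noise
plus a random linear gradient) on an 80×80 grid, four variables, and
draws occurrences cell-weighted by a Gaussian kernel around each
lineage's environmental optimum, jittered within the cell. Defaults —
200 occurrences per lineage, niche breadth 0.5 background SD, 1000
background points — were set from a design analysis of the background
test: the null interval width scales like the background-mean noise
(≈ σ√(2/750) after the 75% jackknife), so occurrence means must be
estimated at least that precisely or pure sampling error masquerades as
divergence. With these defaults the false-divergence rate under a
shared-background null is at the nominal 5% (within binomial error over
200 runs) and a 2σ optimum shift is detected essentially always. With
occurrence samples as small as the motivating study's (≈50–80 records)
the same test is markedly anticonservative — a genuine property of the
background-test design, worth remembering when interpreting real-data
verdicts.

What the generators do *not* emulate: recombination, selection,
more than two descendant populations, spatial sampling bias in
occurrences, and spatial autocorrelation structure beyond the smoothed
fields. Passing calibrations therefore demonstrate estimator
correctness under the stated models, not robustness to those
violations.

## Pipeline, seeds and problem sizes

`pipeline run` executes seq → popgen → demography → network → niche →
morph from one YAML config (each stage skippable; skipping never
changes other stages' results). A master seed derives per-stage seeds
via `SeedSequence([master, stage_index])` with fixed indices, so stages
are individually reproducible and two runs of one config are
byte-identical (report floats are rounded to 10 significant decimals
before serialization for stable JSON). Reports are validated against a
bundled structural schema.

Default analysis parameters mirror the motivating study: 16,000 AMOVA
permutations, 1000 mismatch bootstrap replicates, 95% network
connection limit, 0.80 correlation threshold, 1000 background points,
1000 jackknife replicates at 75%. The test suite's simulation
calibrations use deliberately smaller problem sizes chosen to keep the
whole suite quick while leaving Monte-Carlo error well inside the
asserted bands (e.g. 500 neutral replicates for the Tajima's-D band,
100 fits for τ recovery, 200 runs each for the niche null and power
checks, and a 15-replicate × 100-bootstrap check of SSD type-I
behaviour); each test states its own size.

## Known limitations

- The JC distance is the only model distance; no gamma rate
  heterogeneity or more general substitution models.
- AMOVA is two-level only (no 3-tier designs) and no
  haplotype-frequency F_ST estimators outside the Φ framework.
- The mismatch fit can be weakly identified when θ₁ is effectively
  infinite (flat SSD ridge in θ₁); τ is the reliably recovered
  parameter, which is why calibration targets τ.
- The parsimony-probability formulation conditions on the JC divergence
  re-estimated from each pair's observed differences; it reproduces the
  qualitative behaviour of the classical statistical-parsimony limit but
  is not a line-by-line port of any particular implementation.
- Raster support is ESRI ASCII only; reproject and convert GeoTIFFs
  upstream.
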
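# Methods

## The observation model

A droplet-culture experiment observes a community of sequence variants
(SVs) only through two bulk measurements per sample: an amplicon count
vector (compositional) and a total-16S qPCR concentration (scale, in
arbitrary calibrated units).  The package's estimate of the absolute
abundance of SV *v* in sample *s* is

    abs(s, v) = (count(s, v) + 1) / Σ_w (count(s, w) + 1) × qpcr(s)

with the pseudocount of 1 guarding the subsequent log transform.  Two
strict filters precede this: samples must carry more than 5,000 reads
(shallow libraries are dominated by preparation artifacts), and an SV
enters growth fitting only if its **raw** count is nonzero in more than
5 samples.  Detection is judged before pseudocounting, since
pseudocounts would mark every SV present everywhere.  The order of
operations (depth filter → pseudocount → normalise → qPCR scale) is
fixed; because the qPCR factor is a per-sample scalar, it commutes with
normalisation, which the tests assert as a metamorphic property.

## Poisson loading

Cells are encapsulated at mean occupancy n̄ = ρV.  Droplet occupancy is
Poisson, so p_empty = e^(−n̄), p_loaded = 1 − e^(−n̄),
p_single = n̄e^(−n̄).  The interesting regime is n̄ ∈ [0.1, 0.3], where
10–26% of droplets are loaded and 86–95% of loaded droplets are clonal.
Two inverse problems are supported: n̄ = −ln(f_empty) from counting
empty droplets, and the dilution for a target clonal fraction, solving
n̄e^(−n̄) = c by bisection on [0, 1] (tolerance 1e−12; the equation's
larger root is available behind a flag but experiments dilute toward
clonality, so the smaller root is the default).  The CFU↔OD conversion
constant K is always user-supplied: it is an empirical property of the
inoculum and no default would be defensible.

## Growth kinetics

Per-SV ln-abundance trajectories are fitted with the modified Gompertz
model (Zwietering parameterisation plus an offset):

    y(t) = A·exp{−exp[(μe/A)(λ−t) + 1]} + A₀

- **A** (ln-units): carrying-capacity amplitude; bounds [0, 15], the
  upper bound being the most DNA ever measured in a replicate sample.
- **μ** (1/h): maximum specific growth rate, the slope at the
  inflection; bounds [0, 2.6], the upper bound corresponding to the
  fastest doubling observed in an anaerobe (~15 min; note ln2/2.6 h is
  closer to 16 min — the bound value 2.6 is adopted as given and the
  rounding discrepancy left unresolved).
- **λ** (h): lag time; bounds [−50, 12].  A lower bound of 0 makes
  fitted lags pile up on the boundary, hence the negative floor.
- **A₀** (ln-units): inoculum offset; bounds [0, 15].

A = 0 is handled as the constant-A₀ limit so the exponent never divides
by zero.  Fitting minimises the smooth-L1 (soft-L1) robust loss,
Σ 2(√(1+r²)−1), with scipy's bounded trust-region solver, restarted
from 100 starting points drawn uniformly inside the bound box (the
surface is multimodal; a single start routinely collapses onto the μ
bound).  Restarts with fitted μ ≥ 2.5 are discarded as bound-collapsed;
among the survivors the lowest loss wins, with ties broken toward
smaller μ and then earlier restart order for determinism.  If no
restart survives, the fit is failure-flagged rather than raising.

The growth summary is Δ = y(127 h) − y(0 h) over the sampling window
(hourly for 24 h, then daily to 127 h — 29 distinct time points).  A
taxon counts as growing when Δ ≥ 1.48 ln-units ≈ 2.14 doublings, the
assay's limit of detection.  Saturation timing uses the closed form
t(q) = λ + (A/(μe))(1 − ln(−ln q)); the capacity fraction is taken of
A alone (A is the carrying capacity; the offset is inoculum, not
growth).  The population-level saturation curve is the empirical CDF of
t(q) across retained fits.

## Endpoint assays and threshold calibration

Carbon-utilization endpoint assays are preprocessed per donor: any
sample whose qPCR total falls below the mean no-carbon qPCR is zeroed
(it shows no overall growth), absolute abundances are computed,
replicate medians are taken per condition, and the matched no-carbon
median is subtracted per SV, flooring negatives at 0 — downstream
degrader statistics are nonnegative by construction.

The growth threshold on this scale is assay-specific and is calibrated
against reference data: well-plate OD endpoints of isolates, where
growth means OD strictly above 20% of the isolate's maximum.  The
calibration scans every achievable decision rule — midpoints between
consecutive sorted unique scores plus sentinels below and above all
scores, classifying score ≥ threshold as growth — and maximises
Youden's J = TPR − FPR, breaking ties toward the smallest threshold
(equal J, higher sensitivity).  Tests verify this against brute-force
enumeration.  Kinetics-mode classification uses the fixed 1.48 ln-unit
limit of detection with a closed (≥) comparison.

## Ecology statistics

Primary degraders are SVs growing on at least one polysaccharide;
glucose is a viability control and never counts toward a lifestyle.
Specialists use exactly one polysaccharide, generalists two or more;
the two classes partition the degraders.  Per-donor degrader statistics
(richness or summed abundance) are normalised by the matching
glucose-consumer statistic (PD/GC) to control for viability differences
between samples; both richness- and abundance-based ratios are
provided, labelled.

Hypothesis tests are permutation tests with an add-one correction,
p = (exceed + 1)/(n_perm + 1) (10,000 shuffles by default), seeded and
exactly reproducible:

- **Phylum × lifestyle**: the null permutes phylum labels across SVs
  while keeping each SV's utilization profile (hence lifestyle) intact,
  testing the taxonomy–lifestyle association directly while preserving
  lifestyle marginals; the statistic is the (phylum, lifestyle) cell
  count and "above the observed value" is implemented as ≥.  On small
  instances this null is exactly hypergeometric, which the tests use as
  an enumeration oracle.
- **Combination enrichment**: the null shuffles each polysaccharide
  column independently (preserving per-carbon prevalence, breaking
  between-carbon correlation); each observed utilization pattern gets
  separate over- and under-representation tails.
- **Mantel**: Pearson correlation of off-diagonal distances, one-sided
  (greater) under joint row/column permutation of one matrix.
  Phylogenetic levels are realised as caller-supplied 0/1 same-taxon
  distance matrices per rank.

Cocktail coverage enumerates all size-k polysaccharide subsets and
reports the fraction of degraders growing on at least one member;
coverage is monotone in the subset.  Utilization profiles are clustered
agglomeratively (average linkage, Euclidean distance) with a default
two-group cut — mirroring the single- vs multi-carbohydrate dichotomy —
and the cut height exposed as an override since any fixed cut is a
judgment call.

## The synthetic-data generator

The generator emulates the experiment on the ln-abundance scale, so the
fitted quantity is exactly the latent curve: each growing SV follows a
modified-Gompertz trajectory with parameters drawn strictly inside the
fitting bounds (A ∈ (2, 10), μ ∈ (0.1, 1.5)/h, λ ∈ (0.5, 10) h,
A₀ ∈ (0.5, 5)); nongrowers sit flat at A₀ (μ = 0 and A = 0).  Defaults
mirror the assayed communities: 25% of SVs grow in rich medium, half of
the growers degrade ≥1 polysaccharide, specialists are ~30% of
degraders, inoculum fractions come from a symmetric Dirichlet(0.5) so
most taxa are rare, endpoint assays sample at 48 h (by when most taxa
have saturated), reads are multinomial at depth 30,000 and qPCR carries
mean-one lognormal noise with CV 0.1.  Endpoint replicates additionally
receive independent lognormal biological noise (CV 0.1).  Well-plate
reference screens draw OD ∈ (0.4, 1.0) for utilized carbons (so every
true call clears the 20%-of-max rule even in the noiseless limit) plus
clipped Gaussian noise.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: chimeras and taxonomy
misassignment, PCR amplification bias, droplet coalescence and
polydispersity, cross-feeding in multi-cell droplets, and
session-to-session inoculum drift.  Tests against the generator verify
the estimators under the stated observation model, not robustness to
those artifacts.

## Numerical choices and problem sizes

Bisection tolerance 1e−12 for occupancy roots; Gompertz exponent clipped
at 700 before exponentiation to avoid overflow for t ≪ λ; ROC ties
resolved toward the smallest threshold; clustering rows processed in
SV-id order so zero-distance ties resolve deterministically; all
randomness derives from a single top-level seed through named
CRC32-keyed substreams, so any stage can be rerun in isolation.

Test and verification problem sizes are chosen at desk scale: total
growth recovery uses 50 synthetic taxa on the 29-point sampling design
with 0.1 ln-unit observation noise (median |Δ̂ − Δ| < 0.15 ln-units);
threshold calibration is checked on 100 random instances of up to 50
scores; permutation calibration uses 200 null simulations against the
exact hypergeometric null; the false-growth rate of nongrowers is
estimated over 200 simulated flat taxa (< 5% at qPCR CV ≤ 0.1).

## Known limitations

The Gompertz model is monotone: death phases and diauxic shifts are
outside its expressiveness, and the fitted Δ of such trajectories is a
lower bound on true dynamics.  The endpoint preprocessing subtracts a
no-carbon median, which assumes baseline DNA carryover is
carbon-independent.  PD/GC normalisation is undefined for donors with
no glucose consumers (reported as NaN).  Permutation p-values are
bounded below by 1/(n_perm + 1) and are conservative in the presence of
ties.
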
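# Methods

This note documents the models implemented in `errorthreshold`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data studies do and do not demonstrate.

## Fluctuation analysis

**Model.** A culture grown from a small inoculum to `Nt` cells
accumulates resistance mutations at a constant per-division rate.  The
number of mutation events per culture is Poisson with mean `m`, and a
mutation arising when the population has `n` cells founds a clone of
final size `Nt/n`.  With deterministic exponential growth and a
uniformly distributed cell of origin this gives the clone-size law
P(K ≥ k) = 1/k, and hence the Lea–Coulson form of the Luria–Delbrück
distribution with probability generating function

    G(s) = exp( m · (1−s)/s · ln(1−s) ).

The pmf is evaluated by the recursion obtained from G′ = H′G,

    p₀ = e^(−m),   pₙ = (m/n) Σ_{j<n} p_j / (n−j+1),

which normalises exactly (the exponent series has coefficients
m/(k(k+1))).  The test suite pins this pmf against two independent
routes: numeric FFT inversion of the pgf and a 10⁵–10⁶-replicate
mechanistic simulation of the mutation–growth process.

**Partial plating.** Plating a fraction `z` of a culture (dilutions of
1:10–1:200 are routine for strong mutators) thins each culture's count
binomially.  The thinned distribution is computed exactly from the pgf
identity G_thin(s) = G(1−z+zs): for z ≤ 1/2 the exponent of the thinned
pgf is expanded as a power series (the rational factor has radius of
convergence (1−z)/z > 1 there) and exponentiated term by term; for
z > 1/2 the binomial-thinning convolution against the full-culture pmf
is evaluated directly over a horizon where the binomial kernel has
decayed.  The two routes are algebraically identical and the tests
assert machine-precision agreement on their overlap.

**Estimation.** `m̂` maximises the log-likelihood, found by bounded
scalar minimisation in log m, started from the P0 estimator
m₀ = −ln(fraction of zero cultures) when defined and from the mean
count otherwise; all-zero counts give the boundary maximum m̂ = 0
exactly.  Non-convergence (or a maximum pinned at the expanding search
cap) raises an error rather than returning a default.  Confidence
intervals solve 2[ℓ(m̂) − ℓ(m)] = χ²₁(level) on each side of m̂ by
bracketed root finding; the lower bound is reported as 0 when m → 0
stays inside the acceptance region.  The phenotypic rate is
μ_T = m̂/Nt, with Nt taken equal to the final colony-forming-unit count
(growth from ~1 cell: divisions ≈ final cells).  Grid-search oracles
pin both the MLE (10⁻⁴ relative) and the interval endpoints (10⁻³
relative) in the tests; empirical coverage of the 95% interval over
1000 synthetic 9-culture experiments is 94% at each of m = 0.5, 2, 8.

**Pooling.** Replicate experiments whose Nt values agree within 2-fold
(and share a plating fraction) are merged: counts concatenate, the
likelihood shares one m, and the pooled rate divides by the mean
member Nt.  Groups are formed greedily over the Nt-sorted sequence,
which a dynamic-programming oracle confirms yields the minimal number
of mutually compatible groups.  Discordant sets are kept separate and
flagged for independent estimation.

## Mutation spectra

Substitutions are classified against the reporter coding sequence
(1-based coordinates, coding strand, standard nuclear genetic code):
chain-terminating if the mutated codon is TAA/TAG/TGA, silent if the
amino acid is unchanged, missense otherwise.  Sequence comparison
treats equal-length inputs as per-position substitution scans; a
length difference is attributed to a single left-aligned insertion or
deletion when an end-anchored alignment explains every other base, and
otherwise becomes one `complex` record.  Tallies count events, not
clones (a clone with two scored mutations contributes two events);
complex events pool with indels; silent substitutions — invisible in a
resistance reporter — are excluded from the detectable counts with a
warning.

## Per-base-pair conversion

Chain-terminating substitutions anchor detectability: all of them
inactivate the reporter, and random substitution of a codon yields a
stop in 3 of 64 outcomes.  From a spectrum of M events (B
substitutions of which B_CT chain-terminating, I indels):

    C   = (64/3)·B_CT/B            substitutions only
    C″  = [(64/3)·B_CT + I]/M      substitutions + indels
    τ   = T/C″                      effective target size
    μ_b = μ_T·C″/T = μ_T/τ          per-base-pair rate

For the bundled 484-event mutator spectrum (101 chain-terminating, 341
missense, 42 indels) at a 1773-bp reporter: C = 4.87, C″ = 4.5386
(report tables truncate to 4.53), τ = 391 bp.  Published constants for
the diploid URA3 reporter (C = 8.18, C″ = 6.79, T = 804, plus a ×1.8
cross-locus adjustment to the CAN1 scale) and the mouse ouabain target
(τ = 5 bp/allele × 4 alleles = 20 bp) are treated as opaque inputs,
not recomputed.  Repair-pathway efficiency converts a fold rate
increase F on pathway loss into the percentage of errors the pathway
corrected, 100·(1 − 1/F); pathways acting in series multiply their
folds.

Report rounding follows the conventions of the printed tables: rates
×10⁻⁷ at two significant figures, folds at three, τ to whole base
pairs, threshold-range rates to one significant figure.  Significant-
figure rounding is half-away-from-zero with a 12-digit guard against
binary representation noise.

## Growth grading

Colony-forming capacity is graded on the semi-quantitative scale
+++/++/+/−.  Default band edges: wild-type growth (+++) up to
5×10⁻⁵ mutants per division, slowed growth (++) below 10⁻³, severe
deficit (+) below 2×10⁻³, no visible colonies (−) beyond.  The +/−
edge is not sharply determined by observation; 2×10⁻³ is used because
the weakest strains predicted to be inviable sit there.  Bands are
configurable.

## Error-induced extinction

**Model.** A haploid genome of G genes (default 6000), a fraction f of
them essential (default 1/6), acquires inactivating mutations at a
per-gene per-division rate μ.  Each division produces two daughters,
each independently carrying Poisson(fGμ) essential hits; a daughter
with ≥ 1 hit arrests — it persists as a cell but never divides
(arrest, not lysis, is what is observed).  Colony growth is therefore
a Galton–Watson process with offspring distribution Binomial(2, s),
s = e^(−fGμ).  Extinction probability solves q = (1−s+sq)²; the
critical point is s = 1/2, i.e. μ* = ln 2/(fG) ≈ 6.9×10⁻⁴ for the
defaults — the same order as the ~10⁻³ per-gene threshold at which
colony formation is observed to fail.  Mutation is infinite-sites with
no back-mutation; fitness effects of non-essential hits are not
modelled (a division-time load model was considered and left out: it
does not change the extinction boundary, only colony size at fixed
time).

**Simulation choices.** All cells, arrested included, count toward the
10⁵-cell visibility threshold, but growth requires a surviving
dividing lineage.  The simulation horizon defaults to 150 generations:
a visible colony needs only ~17 doublings, and a finite horizon is
what a plate assay imposes — without it, almost-surely-extinct
critical lineages can pile arrested cells past the threshold and bias
the comparison with the closed form.  Lethal-hit bookkeeping samples
the zero-truncated Poisson exactly from a tabulated pmf (tail
< 10⁻¹²).  Population counts update through aggregate binomial draws,
so trajectories are exact in distribution and bit-reproducible per
seed.  The critical rate is estimated by bisection (geometric
midpoints, common random numbers per evaluation) of the
colony-forming probability against a 1% cutoff; with 400 replicates it
lands within Monte-Carlo and finite-horizon error of μ*, and the
acceptance band [5×10⁻⁴, 1.5×10⁻³] is a consistency check, not an
equality.

## Synthetic data: what it does and does not show

The culture generator reproduces exactly the statistical structure the
estimator assumes (compound-Poisson jackpots, binomial plating), so
recovery and coverage studies validate the estimation machinery, not
the biology: phenotypic lag, death during growth, differential mutant
fitness and plating-induced selection are all absent, and real-data
coverage can be worse than the synthetic 94–95%.  Default designs
mirror the two assay formats (9 excised-colony cultures grown from
single cells; 12 microcultures of 100 founders with 9 plated,
n_final = 10⁷).  Recovery/coverage studies run at n_final = 10⁴ so
that the rare jackpot culture stays within a numerically comfortable
pmf range; the clone-size law is unaffected except for the cap at the
culture size, whose probability mass is ≤ 10⁻⁴ per clone.  The
spectrum generator plants one event per clone at sites compatible with
the requested effect and must round-trip exactly through
diff → classify → tally; its bundled 1773-bp ORF is a synthetic
stand-in for CAN1 (ATG start, no internal in-frame stops), generated
once with a fixed seed.

## Known limitations

* Single-locus estimation only; no phenotypic-lag or
  differential-fitness fluctuation variants, no Bayesian machinery.
* The strain-rate table ships published rounded rates; the underlying
  colony counts are unpublished, so those rates are inputs for fold
  arithmetic, not reproducible outputs.
* The thinned-pmf series route is restricted to z ≤ 1/2 by its radius
  of convergence; the convolution route covers the rest.
* The extinction model ignores checkpoint signalling, cell-cycle
  structure, diploid buffering and suppressor (escape-mutant)
  emergence.
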
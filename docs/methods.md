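# Methods

## Relative fitness from serial-transfer competitions

The W statistic is the ratio of realized natural-log fold-changes of the
two competing subpopulations between a baseline and a later timepoint.
Class densities at each timepoint are reconstructed from the total viable
count and the screened-colony fraction: the screen is treated as binomial
subsampling of the plate (no finite-plate hypergeometric correction —
plates hold far more colonies than are screened), so the bearing density is
`total × n_positive/n_screened` and the two class densities sum exactly to
the total.

Two baselines are supported because serial-transfer designs are ambiguous
about it: `cumulative` (default) compares every timepoint with the assay's
t = 0 counts, `previous` compares with the preceding transfer. For
cumulative accounting across transfers, observed CFU/ml must be multiplied
back by the exact dilutions applied so far; the simulator's observation
series already carries this correction (it cancels in within-culture
proportions and makes log fold-changes additive across cycles), and users
of real data apply the same bookkeeping.

Edge-case policy:

* free class shrinks (negative denominator log) — the signed W is returned
  and the trajectory carries a `free-declined` flag, since the W sign
  convention inverts there;
* zero bearing colonies among the screened at t > 0 — W is reported as the
  NaN `EXTINCT` sentinel with an `extinct` flag rather than −∞: a zero
  screen count bounds the frequency at the plating resolution, it does not
  measure extinction;
* a single informative replicate — sd is reported as 0 with an `n=1` flag
  and a warning, keeping table shapes stable;
* across replicates the sample (n−1) standard deviation is used throughout.

## Serial-transfer growth model (synthetic data)

Three genotypes — ancestral plasmid carrier, compensated carrier,
plasmid-free — share one limiting resource in batch culture:

    dN_i/dt = m_i N_i G,   G = 1 − ΣN/K,

with optional mass-action conjugation (free → ancestral carrier at rate
γ·N_bearing·N_free; transconjugants join the ancestral class because the
plasmid itself carries no compensatory mutation), segregational loss at
division (a fraction ρ of carrier births yields a plasmid-free daughter),
and ancestral→compensated conversion at rate μ per cell per hour. At each
transfer all densities are divided exactly by the dilution factor.
Observation noise enters only through the colony screen (binomial over
`n_screened`); in deterministic mode the screen records the exact expected
count (fractional), which is what lets closed-form recovery checks hold to
machine precision.

Defaults model a succinate minimal-medium culture: m_free = 0.7 h⁻¹, a 10%
plasmid cost (m_bearing = 0.63 h⁻¹), compensated carriers 5% above the free
strain (0.735 h⁻¹), K = 10⁹ ml⁻¹, 24-h cycles, 1:100 transfers, initial
density 10⁷ ml⁻¹ at equal mixing, 200 colonies screened, and
conjugation/loss/compensation off. The default conjugation scale, when
enabled in tests, is chosen so transconjugants stay a negligible
(<0.012%-scale) fraction over one cycle, matching the regime the assay
design assumes. Growth rates are declared model choices — the experimental
system reports only qualitative growth-rate differences — so simulator
output supports property-based checks (rate-ratio recovery, monotone
decline, sweep shape), not numerical reproduction of wet-lab W values,
whose raw counts are not published.

Numerics: the pure exponential regime (K = ∞, no
conjugation/loss/compensation) is advanced by the exact closed form
`N_i(t) = N_i(0)·e^{m_i t}`, making the W = m_bearing/m_free identity hold
to 1e-9; all other regimes use `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-10, atol scaled to the initial total).

The compensatory-sweep scenario (`compensation_sweep_params`) uses
μ = 10⁻² h⁻¹ over 12 cycles. That rate is an aggregate of mutation plus
early within-cycle selection, picked so the sweep completes on the
few-week horizon the assay design probes; per-cell mutation rates alone
would be orders of magnitude lower and would need correspondingly longer
horizons to show the same fall-then-recover shape.

## Plasmid copy number

Copy number is the ratio of mean plasmid depth to mean chromosome depth,
rounded to one decimal half-away-from-zero. Depth ratios rather than
read-count ratios are used because read counts depend on a per-library
effective read length, which is not constant across the bundled panel;
the depth ratio reproduces every published rounded value. The
read-allocation simulator places each read on the plasmid with probability
`c·L_p / (L_c + c·L_p)` (chromosome copy 1, plasmid copy c), using the
published replicon lengths (6,181,873 bp chromosome, 60,099 bp plasmid) as
defaults. At 10⁵ reads the estimator recovers a true copy number of 3
within 0.15 in ≥95% of seeds; the bound is sampling-limited and tightens
as √n_reads.

## Colony morphology

Diameters are summarized by mean, sample sd, and strict threshold
fractions: colonies exactly at the threshold count in neither fraction,
matching the "smaller than"/"larger than" phrasing the morphotype
classification uses. The generator draws truncated-at-zero normals; at the
two morphotype parameter sets (1.01 ± 0.17 mm and 2.10 ± 0.19 mm, n = 200)
the 1.5 mm threshold leaves ≥98% of a sample on its own side in ≥95% of
seeds. Analysis-of-variance comparisons across strains are deliberately
out of scope; the module stops at descriptive summaries.

## Differential expression

RPKM is `reads × 10⁹ / (total_mapped × length_bp)`. The DE rule is a
plain fold-change filter: with two conditions × two replicates, an ORF is
*up* only if all four cross-condition ratios `treatment_i/control_j`
strictly exceed the threshold (default 2.0) and *down* only if all four
fall below its reciprocal. Requiring consistency across every replicate
pairing substitutes for a variance model at n = 2; no negative-binomial
machinery is used because the rule itself is the method under study.
Values are floored at 0.1 RPKM before ratios are formed — the source
procedure does not state its zero handling, so the floor is a declared
choice, exposed as a flag; it caps, never inflates, fold-changes from
unexpressed ORFs.

The expression generator draws baseline ORF means lognormally
(meanlog 3.5, sdlog 1.2 on the natural-log scale — a realistic
several-decade RPKM spread whose low tail stays clear of the floor),
multiplies/divides planted ORF means by the fold, and applies multiplicative
lognormal replicate noise. At noise sd 0.1 replicate correlation exceeds
0.97 (the library-QC regime); at sd 0.2 the caller still recovers ≥90% of
50 planted 4-fold ORFs with ≤5 false positives in ≥95% of seeds. What the
generator does not emulate: count discreteness and depth-dependent
shot noise, length-dependent efficiency, correlated (batch) replicate
error, and operon structure — so passing recovery tests demonstrates the
rule's behavior under clean multiplicative noise, not RNA-seq library
artifacts.

## COG enrichment

Each category's DE count k (of n = 33) is tested against the genome
background (K of N = 5,350) with the upper-tail hypergeometric probability
P(X ≥ k), i.e. the one-sided Fisher exact test for overrepresentation —
one-sided because the question is whether categories are overrepresented,
and that reading reproduces the published significance pattern (exactly O,
L, U below 0.05). The tail is summed directly over the support in log
space via `scipy.special.gammaln`; against exact rational enumeration it
agrees to 1e-12 absolute for all populations N ≤ 60 and to ~1e-12 relative
at genome scale. No multiple-testing correction is applied by default
(matching the per-category raw-P convention of the source analysis); a
Bonferroni option exists. Unassigned ORFs ("–") contribute to n and N but
are never tested as a category. Two-sided testing is available behind a
flag (doubling the smaller tail, capped at 1).

## Band-intensity competition readout

The competitor ratio at each timepoint is the insert-specific band
normalized by the shared single-copy reference band (parI), re-normalized
by the t = 0 value, so the series starts at 1 by construction. The
generator applies independent median-1 lognormal noise per band; for small
coefficients of variation the recovered ratio is unbiased to first order.

## Problem sizes

Default test and driver scales — 2,000-ORF expression matrices, 10⁵-read
allocations, 200-colony samples, 100-seed repetition for distributional
bounds, 20-seed repetition for DE recovery, 6–12 simulated transfer
cycles — were chosen as the smallest sizes at which the targeted
statistical bounds are comfortably non-marginal, and keep the whole suite
in the tens of seconds.

## Known limitations

* The growth model has no demographic stochasticity or lag/stationary
  phase structure; transfers are exact divisions, not Poisson bottlenecks.
* Copy-number estimation assumes uniform mappability and no GC bias.
* The DE caller is a filter, not a test — it reports no error rates, and
  its false-positive behavior under real overdispersion is outside what
  the generator can certify.
* Wet-lab W trajectories depend on unpublished raw CFU counts and are
  checked only at the level of qualitative shape (decline under cost,
  U-shaped recovery with terminal W > 1 under compensation).
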
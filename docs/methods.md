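# Methods

This package implements the computational core of a screen for factors bound
at sites of enriched long-range contact between cis-regulatory elements
(CREs), the pileup machinery used to visualize those "ultra-long-range
interactions" (ULIs), and a polymer model that can generate them by
bridging-induced clustering. Everything is exercised end-to-end on synthetic
data with planted ground truth; no external genomics downloads are needed.

## Contact matrices, balancing, expected, O/E

Binned contact data live in a `BinTable` (0-based half-open bins at fixed
resolution; a point maps to bin `floor(pos / resolution)`) plus an
upper-triangular sparse count matrix. Iterative correction (ICE) finds
per-bin weights equalizing weighted coverage over a chosen pixel scope
(`cis` balances each chromosome independently; `total` uses all pixels;
`trans` only inter-chromosomal ones). Convergence requires the maximum
relative coverage deviation to fall below `tol` (default 1e-5, up to 200
iterations); weights are then rescaled so mean weighted coverage is 1. Bins
with zero coverage, or with log10 coverage more than 5
median-absolute-deviations below the median, are masked and propagate as
NaN. These filter parameters are this package's own defaults — upstream
pipelines delegate them to the balancing tool without stating them.

Expected contact frequency is the mean balanced value per diagonal offset,
computed per whole chromosome (no arm splitting) over all pixels whose two
bins are unmasked — absent (zero) pixels count toward the mean. O/E divides
each pixel by the expected at its offset; undefined pixels (masked bin, zero
expected) are NaN, never zero, so downstream means stay unbiased. By
construction the per-diagonal mean of defined O/E values is 1 (the test
suite asserts this to 1e-9, and checks both expected and O/E pixel-for-pixel
against a dense brute-force oracle on small matrices).

## The contact screen

CRE peaks are merged when closer than 5 kb end-to-start. All same-chromosome
CRE pairs with midpoint separation in [0.1, 10) Mb are enumerated and
stratified into short range [0.1, 1) Mb and long range [1, 10) Mb (midpoint
separation is this package's definition of pair distance; it matches the
flank-0 central-pixel extraction). Each pair's value is the single O/E pixel
containing the two midpoints at 10-kb resolution; pairs on masked pixels are
kept but excluded from testing.

For each factor peak set, CREs are flagged bound/unbound by >= 1 bp overlap
(half-open semantics). Per stratum, pairs bound on both sides are compared
with pairs bound on neither side by the Mann-Whitney U test; the
common-language effect size is F = U / (n1 n2), the probability that a
random bound-pair value exceeds a random unbound-pair value with ties
counted half, so F > 0.5 means enriched contacts at bound pairs. U uses
midranks. The two-sided p-value is exact (full permutation distribution of
U, computed by dynamic programming over doubled midranks, reported as twice
the smaller tail) when n1*n2 <= 200, otherwise the tie-corrected normal
approximation with continuity correction — the same behaviour as the
reference scipy implementation, with which the asymptotic branch agrees to
1e-10 in tests. Datasets overlapping fewer than 500 CREs, or with fewer
than 50 pairs in either group, are excluded and logged with reasons.
Adjusted p-values multiply p by the number of tests actually performed in
the invocation (all dataset x stratum combinations that ran); the
alternative universe (counting strata separately per dataset) would only
change p_adj by the same constant for every test.

A one-sided variant compares, against pairs devoid of any TF, pairs where a
factor is bound on both sides versus bound on one side with at least one
other TF on the far side — pairs with a bare far side enter neither group,
so the comparison never contrasts bound regions with fully inactive ones.

Quartile splitting of scored regions uses stable genome-order rank to break
ties (deterministic output); neighbor annotation counts peaks with
end-to-start gap in [2.5, 100) kb and groups counts as 0, 1–4, 5–10 (5..9),
or >= 10.

## Pileups and stripes

A snip is the square O/E window (default flank 100 kb) centered on the pixel
joining two region midpoints, rows following the lower-coordinate anchor.
Snips are averaged pixel-wise (NaN ignored; a pixel missing in every snip
stays missing) per separation stratum with half-open breaks at 0.1, 1, 10,
25, 100 Mb. Corner normalization divides the grid by the mean of the two
`corner_size x corner_size` blocks at the top-left and bottom-right — the
blocks along the diagonal direction, i.e. the local background at the two
anchors — and refuses with a diagnostic when the corner mean is zero or
undefined. Cross-group pileups take only A–B pairs and transpose snips of
reversed-order pairs so set A always maps to rows. The per-pair "corner
stripe" walks the central column from the top edge to the central pixel and
then the central row out to the right edge (length 2*flank_bins + 1, central
pixel at the midpoint); the exact pixel path of the original analysis is not
published, so this L-path is a documented convention of this package.
Central-pixel ECDFs report the exact-zero fraction separately because
long-range pixels are mostly zero at realistic depth. A shifted-control mode
normalizes by separation-matched random windows (5 seeded shifts per pair)
instead of the expected model.

## Synthetic data with planted truth

The generator produces per-chromosome Poisson counts with intensity
`depth * d^-alpha` (d = separation in bins >= 1; alpha defaults to 1, the
canonical contact-decay regime; depth 100 at 10-kb bins gives one mean count
per pixel at 1 Mb, matching the sparsity regime of deep Hi-C at these
distances). A set of anchor CREs multiplies intensities by `e` (default 2)
when both bins hold anchors and by `s` (default 1.4) when exactly one does
(the stripe). Enriched counts are added as independent Poisson increments,
so enriched pixels are exactly Poisson of the enriched intensity. CREs
occupy distinct bin centers (one per bin) so central-pixel extraction is
unambiguous; 300 anchors sit among 2100 CREs. The planted factor binds
anchor CREs with probability 0.9 and background CREs at 0.2 (a real hit
factor binds many CREs genome-wide; it must also clear the >= 500-CRE
inclusion filter). Decoys bind every CRE with probability 0.7 independent of
anchor status — the null the screen must not reject — plus optional uniform
noise peaks placed >= 10 kb from anchors. The background CRE count sets the
effective sample size of the decoy null: bound flags are shared across all
pairs touching a CRE, so F fluctuates on the scale of CRE counts, not pair
counts.

Balancing and the planted signal. The generator plants no visibility bias,
but anchor rows genuinely carry ~(s-1) more coverage; ICE, which assumes
equal visibility, therefore absorbs a large part of the planted signal into
the weights (measured: ~9% central deflation at s=1, ~30% at s=1.4, with
stripes flattened to ~1). Recovery studies consequently run on raw counts
(unit weights); the balanced route remains the default for real data, where
the same flattening is a known mild cost of ICE on genuine enrichment, and
is itself validated by the balancing test suite. What passing recovery
tests shows is that the screen and pileup engines faithfully measure the
structure present in their input; they do not show that ICE is harmless on
maps whose enrichment violates equal visibility — it is not.

What the generator does not emulate: trans contacts, homolog phasing,
TADs/compartments (optional block/checkerboard factors were considered and
left out of the core path), overdispersion beyond Poisson, and
visibility/mappability bias. Conclusions about those require real data.

## Polymer model

A chromatin fiber of N beads (3 kb and ~30 nm per bead; sigma = bead
diameter is the length unit, k_BT the energy unit, tau = sigma^2/D the time
unit) is a bead-and-spring chain: stiff harmonic bonds (k = 50 k_BT/sigma^2,
rest length sigma), optional Kratky-Porod bending stiffness (default 0,
fully flexible), and purely repulsive WCA cores between all particles.
`n_site_beads` beads, uniformly placed, are high-affinity sites for one of
`n_types` binder colors (types round-robin over a shuffled order, so counts
differ by at most one; 172 sites over 5 types gives 35/35/34/34/34).
Diffusing binder beads bind all chromatin with depth `eps_nonspecific`
(default 3 k_BT) and own-color sites with `eps_specific` (default 8 k_BT).
The attraction is a smooth cosine-squared well from the core radius
2^(1/6) sigma out to the 1.8-sigma cutoff, flat at full depth against the
core: unlike a Lennard-Jones well, its curvature grows only as ~10.7 eps /
sigma^2, so wells of 8-12 k_BT remain numerically stable at the working
timestep (an LJ well of the same depth has curvature ~57 eps and ejects
bound binders by integrator oscillation — binding strengths would silently
saturate). Binders never attract each other — clustering, when it appears, is
bridging-induced: a multivalently bound binder loops chromatin, raising the
local concentration of chromatin and sites, which recruits more binders.
Binders switch stochastically between an interacting "on" state and a
purely repulsive "off" state (rates k_on, k_off), implementing
binding/unbinding turnover.

Dynamics are overdamped Brownian (Euler-Maruyama, unit friction and
temperature, timestep 0.005 tau). A per-pair force cap (50 k_BT/sigma)
soft-cores the WCA potential so the integrator is stable at this timestep;
this is the usual coarse-grained compromise and does not change the
qualitative phase behaviour. The chain plus binders live in a non-periodic
cube with soft harmonic walls sized so the chromatin number density is 0.1
sigma^-3. A non-periodic box was chosen over periodic images because every
observable here is a single-chain quantity: with minimum-image contacts a
chain spanning the box registers contacts with its own periodic images,
which have no genomic identity, and rigid-motion invariance of the virtual
observables would be lost. Initialization is a random walk at bond length,
folded into the box, followed by a 2000-step capped-force push-off with
attractions off; binders start uniform. All randomness flows from one seed;
identical seeds reproduce trajectories bitwise under a fixed configuration.

Interaction strengths for the desk-scale ensembles (see
`ulitools.studies.FULL_MODEL`) sit in the standard
bridging-induced-attraction regime: specific 8 k_BT, nonspecific 3 k_BT,
cutoff 1.8 sigma, with turnover slow relative to the run (k_off = 0.001 /
tau) so a formed bridge persists. In 1500-tau runs this produces
reproducible site occupancy (~0.6-0.75), stable long-range site-site
bridges, and binder cluster growth; the quantitative parameters of the
original model are not published in the main text, so the turnover rates
and run lengths are this package's own choices. The ablation
(`eps_nonspecific = 0`) and control (all attractions 0) conditions differ
only in the attraction depths.

The scaled-down test preset uses 500 beads, 20 sites, 2 types, 20 binders,
300,000 steps (1200 tau) sampled every 1000 steps; ensembles of 5 seeds per
condition complete in roughly 12 minutes on one core. These runs are far
from full equilibration — they probe the onset of bridging, not its steady
state — which is why ensemble statistics are compared by direction (growth,
enrichment above 1, ablation ordering) rather than by magnitude.

## Virtual observables

All distances are plain Euclidean on the simulated coordinates, restricted
to the second half of each trajectory (time >= n_steps * dt / 2). Virtual
Hi-C counts a contact whenever two chromatin beads are within 90 nm, binned
at 7 beads (21 kb), cumulative over frames and runs. Virtual pileups count
contacts within 54 nm at single-bead (3 kb) resolution in windows around
site pairs more than 100 beads apart; values are raw counts. Bead-level
site-contact enrichment compares contact totals of site-bead pairs (> 100
beads apart) with separation-matched non-site bead pairs; the binned
version splits site-bin pairs into homotypic (sharing a color) and
heterotypic and compares each with separation-matched non-site bins.
Virtual FISH takes the center of mass of the 17-bead (51-kb) window around
each site (all beads weighted equally), records pairwise window distances
per frame, and calls colocalization below 200 nm. FISH pair sets span all
separations above 20 beads (the smallest with non-overlapping windows):
in a confined box the mean inter-window distance saturates with genomic
separation, so the short-to-intermediate range carries the
distance-versus-separation trend that the scaled ensembles probe. Pairs whose windows run
off the polymer are skipped and logged. One trajectory contributes one
effective configuration at long correlation times, so enrichment ratios are
heavily right-skewed per run; the tests therefore pool frames within runs
and use sign tests across seeds (one-sided, the direction being specified in
advance) rather than per-run magnitudes.

The full-scale configuration (5000 beads / 15 Mb, 172 sites, 5 types, 200
binders) and an ensemble driver for published-scale virtual FISH are
provided (`analysis/06_full_scale_fish.py`); at roughly 180 runs of hours
each on one core this is an extended study, not part of the default test
path, and its colocalization percentages at 5.9 and 1.7 Mb are not asserted
anywhere.

## Numerical and design choices

- Exact Mann-Whitney p-values define the two-sided p as twice the smaller
  tail (capped at 1), the standard convention for discrete permutation
  distributions; ties make the U distribution asymmetric, so the two tails
  are computed explicitly.
- Quartile and neighbor-group ties resolve by stable genome order;
  reruns are byte-identical.
- Stratum intervals are half-open everywhere; a pair exactly at max_sep is
  excluded, one exactly at min_sep included.
- Pileup means ignore NaN; aggregation before or after corner normalization
  commutes with global scaling (asserted).
- ICE on an exactly balanced matrix returns weights 1; rank-1 matrices
  recover the closed-form 1/v weights to 1e-6 relative (asserted).
- Cluster detection is single-linkage on binder-binder distance < 1.3 sigma.
- Derived seeds stay below 2^31; every stochastic function takes an explicit
  seed or Generator.

## Known limitations

- The screen's p-values treat CRE pairs as exchangeable units, but pairs
  sharing a CRE are correlated; p-values are therefore anti-conservative
  (decoys occasionally reach nominal significance while their effect sizes
  stay at 0.5). Effect-size ranking, which the recovery study scores, is
  unaffected. The original analysis has the same property.
- Desk-scale polymer ensembles probe direction, not magnitude; full-scale
  quantitative readouts need the extended driver and long runs.
- The triplet-text reader loads whole matrices into memory; genome-scale
  real datasets would need a chunked or container-backed adapter (the
  optional standard-container adapter is not implemented).
- Trans-contact analysis is limited to scalar expected per chromosome pair;
  the generator produces no trans contacts to exercise it beyond unit tests.
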
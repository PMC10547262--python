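# ulitools

Active cis-regulatory elements (CREs) — promoters and enhancers — contact
each other in Hi-C/Micro-C maps at genomic separations of up to tens of
megabases, independently of cohesin loop extrusion and polycomb. This
package implements the computational machinery to detect, quantify and
model these ultra-long-range interactions (ULIs):

* **Contact-matrix core** — binned sparse contact matrices from plain-text
  triplets, ICE balancing (cis / total / trans scopes), distance-decay
  expected models, observed/expected (O/E) matrices.
* **Factor screen** — merge CREs, enumerate CRE pairs at short (0.1–1 Mb)
  and long (1–10 Mb) range, flag binding per factor peak set, and rank
  factors by the Mann–Whitney common-language effect size
  `F = U / (n1 · n2)` — the probability that a bound–bound pair has higher
  O/E than an unbound–unbound pair (ties half), so F > 0.5 means enriched
  contacts at bound pairs. Bonferroni-adjusted p over all tests performed.
* **Pileup engine** — distance-stratified average O/E windows around region
  pairs, corner normalization, cross-group orientation flipping, per-pair
  "corner stripes", central-pixel ECDFs, shifted-control normalization.
* **Polymer model** — bead-and-spring chromatin (3 kb / 30 nm per bead)
  with diffusing multivalent binders that bind sites of their own color
  strongly and all chromatin weakly, with no binder–binder affinity;
  bridging-induced clustering emerges. Overdamped Brownian dynamics with a
  numba kernel; virtual Hi-C (contacts < 90 nm, 21-kb bins), virtual
  pileups (< 54 nm, 3-kb bins, raw counts) and virtual FISH (center-of-mass
  distances of 51-kb windows, colocalization < 200 nm) read out the
  trajectories.
* **Synthetic data generator** — power-law Poisson contact maps with
  planted anchor enrichment (central factor e, stripe factor s) and factor
  peak sets with controlled anchor association (plus independent decoys),
  so every stage is testable end-to-end against known truth, offline.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

Generate a synthetic study and screen factors against it:

```
python analysis/01_generate_synthetic_data.py --seed 1
python analysis/02_contact_screen.py --seed 1 --n-seeds 5
```

which prints

```
0.1-1Mb: planted F = 0.618 (rank 1 in 5/5 seeds), decoy |F-0.5| max = 0.015
1-10Mb: planted F = 0.533 (rank 1 in 5/5 seeds), decoy |F-0.5| max = 0.008
planted factor tops both strata in 100% of seeds
```

The planted factor (bound at 90% of anchors) shows F well above 0.5 at both
short and long range and outranks every decoy in every replicate, while
decoys — which bind CREs independently of anchor status — sit at the null
F = 0.5 to within ~0.015. `analysis/03_pileups_and_stripes.py` confirms the
pileup route: corner-normalized central pixels recover the planted e = 2
and stripe arms the planted s = 1.4 within a few percent, over a flat
background.

Run the bridging-model ensembles (full model, specific-only ablation,
no-attraction control; ~10 minutes):

```
python analysis/04_polymer_ensembles.py --seed 2 --n-seeds 5
```

```
largest binder cluster (late): full 2.13 vs control 1.19
site-contact enrichment: mean 4.86, 5/5 replicates > 1 (one-sided sign test p = 0.031)
off-center stripe counts/pair/frame: full 0.0027 vs specific-only 0.0009
virtual Hi-C (>300 kb, per-run mean): homotypic 3.98, heterotypic 1.83
```

Binder clusters grow only when attraction is on; binding sites more than
100 beads (300 kb) apart contact each other several-fold more than
separation-matched non-site regions in every replicate; both same-color
(homotypic) and different-color (heterotypic) site pairs are enriched, as
expected for mixed bridging clusters; and deleting the weak nonspecific
attraction removes most of the stripe signal while the central site–site
enrichment persists. `analysis/05_virtual_fish.py` shows colocalization
(< 200 nm) of site-pair windows becoming rarer with genomic separation.
`analysis/06_full_scale_fish.py` is the long-running full-scale (5000-bead)
configuration and is not part of the default test path.

## Command-line interface

`uli synth | screen | pileup | simulate` wrap the same library functions
for ad-hoc use on files (bin-table + triplet TSVs, BED/narrowPeak peaks);
every run writes a `manifest.json` with resolved parameters, seed, and
input checksums. The numbered scripts under `analysis/` are the canonical
drivers.
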
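# Methods

## Model

DNA is a one-dimensional lattice with a 1-bp lattice constant.  Binding
species are rigid rods: the nucleosome covers 147 bp (configurable, mainly
for tests), a TF covers the width of its position weight matrix, and a
poly(A/T) "factor" covers its tract length.  Placements may not overlap
(hard-core exclusion) and the ensemble is in thermodynamic equilibrium: a
configuration with particles t starting at positions i has weight
`∏ c_t exp(−γ_t E_t(i))`.  The model is purely equilibrium — remodeling
enters only through its effect on the energy landscape (below), not through
kinetics.

The partition function and all start-probability marginals are computed
exactly with prefix/suffix recursions (transfer-matrix style), in the log
domain with pairwise log-sum-exp.  The forward and backward totals are the
same quantity computed two ways; `solve` checks them against each other at
1e−9 relative tolerance and checks the hard-core feasibility bound
(total occupancy ≤ 1) at every base pair.  Occupancies are clipped to
[0, 1] only within 1e−8 of the boundary; anything larger raises, because it
indicates a real defect rather than round-off.  A brute-force configuration
enumerator provides an independent exact oracle for systems up to ~30 bp
and is used in the test suite, never in production paths.

Chromosomes are independent lattices with no wrap-around; genome-level
quantities are length-weighted aggregates.

## Energy landscapes

* **PWM factors.**  `E0(i) = −Σ_j log w(j, base_{i+j})`.  Both strands are
  scanned by default (TFs bind double-stranded DNA) and the better-scoring
  orientation is kept per start, so each factor stays a single species on
  the lattice; a `both_strands=False` switch reverts to single-strand
  scanning.  A start is bindable only where the window's log-odds score
  against a uniform background passes a cutoff — by default 60% of the
  motif's maximum achievable log-odds, configurable per PWM.  Windows
  containing N or a zero-probability base never bind.
* **Poly(A/T) factors.**  One species per tract length k (default 5–9);
  bindable exactly at pure homopolymer A_k or T_k windows.  Mixed A/T
  windows do not qualify: these species model RSC recruitment to
  uninterrupted tracts, and interrupted tracts are a documented blind spot
  of that definition.
* **Nucleosome.**  Either a supplied per-position probability track
  (`E0 = −log P`) or energy track, or a built-in flat surrogate (no
  sequence preference at all).  The test fixtures also provide a smooth
  random landscape (Gaussian-filtered white noise, labelled synthetic) so
  that specificity γ is identifiable without any dinucleotide model.
* **Normalisation.**  Every track is shifted so `⟨e^(−E)⟩ = 1` over its
  bindable starts.  The shift is degenerate with c, so this is purely a
  convention that keeps concentrations of different factors on comparable
  scales; a shift-invariance property test pins it down.

Coordinates are 0-based half-open throughout the code and in BED output;
bedGraph and BED writers/readers follow the usual UCSC conventions, wig
input is fixed-step only.

## NDR annotation

References arriving as log-ratios are mapped to absolute occupancy
`Y = c·e^(γ·Y_L)` with the genome mean pinned to 80% (the near-saturating
in vivo nucleosome density) and `max Y ≤ 1`, taking γ as large as the
ceiling allows (bisection on the ceiling constraint, which is monotone in
γ; a configurable cap, default 10, applies when the ceiling never binds,
e.g. constant tracks).  Callers are expected to remove gross outliers
before the transform.

Annotation discretises the track with lines descending from 80% in 6.78%
steps and applies three rules to each maximal dip below 80%: width at the
73.2% line (outermost crossings, interior bumps included) strictly greater
than 110 bp; flank steepness dx — the distance from the 80% crossing to the
crossing of the lowest line the dip reaches — strictly below 100 bp on at
least one flank (each flank is measured separately and the steeper one must
qualify); and merging of accepted NDRs whose centers lie within 125 bp.
The NDR interval spans the lowest-line crossings; its reported length is
the contiguous extent below the 66.43% cutoff (mean − 2 SD) around the
dip's minimum, which generally extends beyond the interval itself.  Tracks
shorter than one nucleosome yield an empty set with a warning.

The "modified" reference pins occupancy to zero inside each NDR interval
and re-solves the transform on the remaining positions so the genome mean
returns to 80%.

Prediction scoring: a reference NDR counts as hit when a contiguous run of
predicted occupancy below the cutoff, at least 50 bp long, overlaps it (the
50-bp floor suppresses single-bp dips; configurable).  Because the paper
trail for hit bookkeeping is genuinely ambiguous, both a per-NDR view
(P_NDR, hit/missed lists) and a per-bp view (FPR over non-NDR positions,
AUC of 1 − occupancy against per-bp NDR labels) are reported.  Note that
per-bp FPR charges the prediction for depleted flanks just outside the
labelled intervals even when the reference itself is depleted there; it is
a conservative bookkeeping, not a calibrated error rate.

## Cooperativity

Sites with inter-motif gaps strictly under `max_gap` (default 12 bp; 147 bp
is the documented alternative) chain into clusters by single linkage.
Within groups of mutually overlapping motifs only the top two scores
survive (two overlapping TFs may co-bind in rare cases; more cannot) —
hard-core exclusion on the lattice is still always enforced; the pruning
only decides which sites receive the bonus.  The bonus itself lowers each
clustered site's energy by a constant strength (equivalently multiplies its
weight by `e^(γ·strength)`); a variant raises the owning factors' γ
instead, matching an alternative reading of the construct, and is exposed
as `mode="specificity"`.  The bonus deliberately breaks the track
normalisation at clustered sites, and it lowers genome-average nucleosome
occupancy, so the nucleosome (c, γ) should be re-fit after applying it.

## Remodeling

Each bound factor adds a Gaussian barrier `h·exp(−(x−x0)²/(2w²))` to the
nucleosome energy.  `w` is the Gaussian standard deviation (the looser term
"width" in the literature is ambiguous; this choice is the one the closed
form uses).  The barrier centers on the motif midpoint and is indexed by
the dyad each nucleosome start would place at x0 ± (start + 73); a
start-indexed variant is available.  The Gaussian is truncated beyond 4 SD
(neglected tail mass < 3·10⁻⁴).  Barriers from adjacent sites superpose.

Binding is probabilistic, so the landscape is simulated `repeats` times
(default 100): each eligible site — binding occupancy above 0.0022, scope
either all TFs or a named subset such as the RSC-recruiting species —
contributes its barrier independently with probability equal to its
occupancy, the equilibrium is re-solved, and the nucleosome occupancy is
averaged.  One seeded generator drives all draws, so a fixed seed gives a
bit-identical average.  Identical inclusion patterns are solved once and
cached, which makes large repeat counts cheap when sites are near-saturated.
Barriers do not trigger further binding/remodeling rounds (no secondary
remodeling).

## Fitting

The objective is the per-bp RMSD between total nucleosome occupancy and the
reference over the training chromosomes; non-finite model output maps to
+∞ (a rejected move).  Bounds — c ∈ [0, 10³], γ ∈ [0, 5], h ∈ [−50, 50]
k_B·T, w ∈ [1, 500] bp — are enforced by smooth transforms (log for c,
logistic otherwise) so the simplex is unconstrained.  The annealing
schedule is geometric: T₀ = 1 objective unit, cooling factor 0.9, 50
temperatures by default, a bounded Nelder–Mead run from a perturbed restart
at each temperature, Metropolis acceptance, then a final polish from the
best point.  These schedule constants are declared defaults, not derived
quantities; every one is configurable.  A zero-iteration budget returns the
initial parameters with their metrics.

Cross-validation splits at chromosome granularity (70/30 by default, at
least one chromosome per side, ≥2 chromosomes required), repeated over
shuffles (default 5); the winning shuffle has the best held-out P_NDR, with
held-out RMSD as tie-breaker and fallback when the held-out set contains no
NDRs.  Remodeling fits hold the TF (c, γ) fixed and vary nucleosome (c, γ)
plus (h, w).  A driver ranks candidate factors by single-factor held-out
P_NDR and re-fits after each addition, for incremental factor-set curves.

## Synthetic fixtures

The generator emulates a small yeast-like study: a few chromosomes of
tens of kb, i.i.d. background at 38% GC, planted motif instances and
poly(A/T) tracts at recorded coordinates (overlaps rejected unless
requested), and reference occupancy either forward-simulated from a truth
system (plus additive Gaussian noise, clipped to [0, 1] — the noise SD is a
free choice since real measurement noise is uncharacterised here) or drawn
as flat-bottomed cosine-ramp dips on a 0.85 background, whose half-width
and flank directly control which annotation rules they pass.  What the
fixtures deliberately do not emulate: MNase digestion bias, read-level
counting noise, dinucleotide periodicity of nucleosome affinity, and real
TF motif composition.  Passing tests therefore demonstrate correctness of
the machinery and recoverability under the stated noise model, not
predictive accuracy on real chromatin.

## Problem sizes and defaults in the acceptance script

`scripts/acceptance.py` uses a 4 × 5 kb planted-motif genome with one TF
(consensus sites every 900 bp), a smooth synthetic nucleosome landscape,
nucleosome concentration calibrated by bisection to 80% mean occupancy,
reference noise SD 0.005, a 2-shuffle fit (6 temperatures, 120 simplex
iterations per stage), 50 remodeling repeats at h = 16 k_B·T, w = 57 bp,
and 50 enumeration cross-check systems.  These sizes were chosen as the
smallest at which every quantity is stable across seeds; all scale up
linearly in L.

## Known limitations

* The equilibrium model cannot represent kinetic phenomena (e.g.
  remodeling-rate competition); barriers are an effective-energy stand-in.
* Cooperativity is uniform across factors; no pairwise interaction matrix.
* Interrupted poly(A/T) tracts (e.g. T₄ACT₇-like sequences) are invisible
  to the homopolymer definition.
* The per-bp FPR depends strongly on how reference NDR intervals are
  bounded (see above) and should be compared only within one labelling
  convention.
* `fit_parameters` optimises a non-convex objective; with tiny budgets it
  returns best-so-far with `converged=False` rather than failing.
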
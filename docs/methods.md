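# Methods

This note documents the models implemented in `medteg`, the choices made
where the design was genuinely open, and what the simulation studies do and
do not demonstrate.

## Coordinate conventions and geometry

Locations are visual-field degrees: x positive rightward, y positive
superior; for the right eye the temporal field (and the blind spot, at
(+15, −1.5)°) is at positive x and the nasal field at negative x. The left
eye is the x-mirror. The 24-2 constructor places 54 points on a 6° lattice
offset 3° from both meridians (points within 24° eccentricity plus the
two-point nasal step at 27°); the 10-2 constructor places 68 points on a 2°
lattice offset 1° from both meridians within 10°.

**Bounded Voronoi tessellation.** Cells are built by intersecting
perpendicular-bisector half-planes (nearest nuclei first, with an early
exit once remaining nuclei are more than twice the current cell radius
away) and clipping to a convex bounding region. The default region is the
±30° box — the testable field of a standard perimeter. The bound is not a
formality: a candidate's cell area is its information *footprint*, and
area outside the testable field must earn no credit. For the same reason,
when candidates are restricted to the grid's convex hull (the default),
the credited area `A_c` is the candidate's cell *clipped to that hull*;
otherwise cells on the hull rim sweep up unbounded outside area and the
selection degenerates to orbiting the rim. `geometry.sibson_weights`
always reports the raw bounded-region cell area; the hull clip is applied
by the scoring layer.

Coincident Voronoi vertices (4+ cocircular nuclei, as produced by every
regular lattice) are merged within the dedup tolerance ε = 0.01°, far
below perimetric stimulus size. Candidates within ε of a tested location
are dropped.

**Sibson weights.** Weights are normalized stolen areas,
`w_i = A_i / Σ A_i`. Because the old cells tile the region and the
candidate's new cell is a subset of it, `Σ A_i = A_c` exactly for every
candidate, so this coincides with `A_i / A_c` while remaining robust to
floating-point slack at the region boundary.

**Hemifield masking.** Retinal nerve-fiber bundles terminate at the
horizontal raphe, so as an option a candidate's PMF can be interpolated
from its own hemifield only: neighbors across — or on — the meridian get
zero weight before renormalization (with graceful fallbacks: on-meridian
neighbors are readmitted if no strictly same-side neighbor exists, and the
full neighborhood if even that is empty; a candidate exactly on the
meridian uses all neighbors). The mask is off by default and enabled in
the hemifield-loss simulation, whose pathology is structured by the raphe.

## Bayesian threshold machinery

Thresholds live on a discrete domain (default 0…40 dB in 1 dB steps, the
same for stimuli). The frequency-of-seeing curve is a modified cumulative
Gaussian, decreasing in stimulus level x because higher dB is dimmer:

    p_seen(x; µ) = γ + (1 − γ − λ) · (1 − Φ((x − µ)/σ))

with guess rate γ = 0.02, lapse rate λ = 0.05 and spread σ = 1.5 dB by
default; σ = ∞ is supported and makes every stimulus uninformative.
Entropy is Shannon entropy in bits (base 2 is arbitrary; all decisions are
argmax/ratio-based and base-invariant). The one-trial-ahead expected
entropy reduction is

    E(ΔH) = H(prior) − min_x Σ_r P(r | x) · H(posterior | x, r)

minimized over the stimulus domain with ties broken to the lowest dB for
determinism. `E(ΔH)` is computed by exact enumeration over
(stimulus × response × threshold), matching a naive triple loop to
machine precision; likelihood tables are cached per (domain, σ, λ, γ).

**Starting priors.** A tested location starts from a ZEST-style bimodal
prior: a normal mode centered on the age-normal value (s.d. 5 dB) mixed
with a broad low-sensitivity mode (20% mass, centered 2 dB, s.d. 8 dB).
This matters: from a *uniform* prior, the short per-location trial budget
used in the simulations leaves ~3 bits of residual entropy everywhere,
which drowns the spatial uncertainty structure the selection rule is
designed to exploit. A location chosen dynamically instead starts from its
Sibson-interpolated PMF — the same PMF that scored it.

**Per-location testing** uses entropy-optimal stimulus placement for a
fixed budget of 4 presentations (configurable), a common staircase budget.
The posterior mean is the reported DLS estimate.

## Scoring and selection

For each candidate with composite weight ω > 0 (zero-weight candidates are
discarded before any Bayesian work, since they can never win):

    score = ω · E(ΔH) · A_c        (or ω · H · A_c in the H-max variant)

Weight rules are multiplicative and clamped to [0, 1], preserving hard
zeros while allowing gradation: inside-hull, device-range, horizontal- or
vertical-meridian exclusion (default half-width 1°), blind-spot exclusion,
eccentricity decay ω = 1/(1 + d/d₀) with d₀ = 10° (a bounded stand-in for
"inversely proportional to distance from fixation", which is singular at
0), and bilinear lookup into a gridded structural map. σ may be supplied
as a field σ(x, y) so the score can prefer regions with more reliable
responses. Argmax ties break to the candidate nearest fixation, then list
order; top-N selects from a single scoring pass without re-tessellating;
stochastic mode samples proportionally to score with a seeded generator.

## Synthetic observers

The ground truth is a "hill of vision": µ(x, y) = 33 − 0.08·ecc −
0.0006·ecc² dB (≈30 dB at 27° eccentricity) and σ(x, y) = 1.5 dB, each
plus smooth seeded jitter (s.d. 1 and 0.25 dB, σ floored at 0.5 dB)
generated by a random-cosine Gaussian field with a 6° length scale — a
parametric stand-in for a normally sighted young adult, not a normative
claim. The blind spot is a 2.5°-radius disc at (±15, −1.5)° where
responses occur at guess rate. Defects compose onto the surface:

- **Central scotomata** — discs of configurable depth (overlaps take the
  deepest loss, so composition is order-independent);
- **Hemifield loss** — *total* loss: µ reads 0 and, because "no measurable
  sensitivity" means exactly that, responses occur at guess rate rather
  than at the ≈50% a 0 dB threshold would grant the brightest stimulus;
- **Regional loss** — uniform depth inside a polygon.

µ is clamped to [0, 40] dB. Responses are Bernoulli draws from the
frequency-of-seeing curve at the observer's true µ and σ; every source of
randomness descends from the run seed, so runs replay exactly.

Structural weight maps are gridded fields in [0.01, 1] with bilinear
lookup, per-lattice-cell Gaussian jitter (s.d. 1, clamped back to
[0.01, 1]) and an x-flip transform (an involution) to model a
wrong-eye/wrong-orientation error.

## The simulation studies

All four studies use λ = 0.05, γ = 0.02, spatially varying true σ that the
estimation engine is assumed to know, blind-spot exclusion among the
weight rules, hull-restricted candidates, and 200 runs by default (the
test suite and acceptance script use 100 or fewer; problem sizes were
chosen so a full study runs in minutes on one CPU).

1. **Enhanced perimetry.** 24-2 baseline on an observer with three
   adjacent macular locations ((3,3), (9,3), (3,9)) depressed by
   10–20 dB (drawn per run) over 3° discs; five dynamic additions. Metric:
   additions "in or around" the loss, i.e. within the lossy discs dilated
   by 3° (half the 24-2 spacing). Result: ≈80% of additions land there.
2. **Personalized perimetry.** Ten seed points, five per hemifield
   ((±9,±9), (±9,±21), (−21,±9)), on an observer with total superior
   hemifield loss; twelve additions with the raphe mask enabled. Metric:
   percentage excess of points in the preserved relative to the nonseeing
   hemifield over all 22 locations (meridian points count as preserved —
   they see). Result: ≈ +22%.
3. **Structure-guided perimetry.** Regional loss of 12 dB in the
   upper-left box x ∈ [−27, −3], y ∈ [3, 27] (comfortably past the 8 dB
   criterion that defines "damaged"); structural weights 1.0 inside /
   0.01 outside on a 2° lattice; ten seeds, fourteen additions. With the
   clean, correctly oriented map ≈99% of additions fall in the damaged
   region; with noise ≈49%; with noise plus x-flip ≈30%.
4. **Indeterminate-duration perimetry.** Per run a location budget drawn
   uniformly from 11–54 (paired across arms for variance reduction): a
   random-24-2 arm versus ten seeds plus dynamic additions, each scored by
   the sum of squared residuals between a piecewise-linear (Delaunay)
   surface through the estimates and the true hill, evaluated on a 0.5°
   lattice inside the tested hull, excluding points within 1° of the blind
   spot. Per-arm fits of SSR = −a·log₁₀(n) + b and stratified two-sample
   t-tests summarize the budget dependence.

A maximum-gradient baseline (same candidates, same Sibson initialization,
scored by the largest estimated-threshold difference among a candidate's
natural neighbors) and a random-24-2 policy support the comparisons; the
gradient policy clusters its additions far more tightly (mean
nearest-neighbor distance ≈1.5° vs ≈4.7° for the entropy policy in study
4). The gradient score has no way to absorb prior structural weights, so
study 3 has no gradient counterpart.

## What the simulations do and do not show

The synthetic observers have stationary psychometric functions, a σ that
does not covary with sensitivity, sharply bounded defects, and smooth
jitter in place of real inter-subject variability; none of that is true of
patients. Passing tests therefore demonstrate the internal correctness and
the qualitative behavior of the selection rule — not clinical utility.
The magnitudes of the behavioral summaries (the hemifield excess and the
flipped-map residual targeting in particular) are sensitive to conditions
with no single canonical value: the per-location trial budget, the
starting prior, the seed layout, and the defect geometry. With the 4-trial
budget the hemifield excess is ≈ +22%; at 8 trials per location the same
code yields ≈ +140%, because dead-field posteriors pin to the domain floor
and stop promising information. These sensitivities are reported as
measured rather than tuned to any particular figure.

## Numerical notes and limitations

- Geometry is exact shapely polygon arithmetic; areas agree with
  Monte-Carlo assignment oracles to sampling error and with an
  independent qhull-plus-mirroring construction to 1e-9.
- Degenerate inputs fail loudly: <3 or collinear points, candidates
  coincident with tested locations, unnormalized PMFs, σ ≤ 0.
- An empty candidate set (every vertex outside the hull, or all weights
  zero) is a signal to the caller, not an exception, except in
  `select_next`/`grow_grid` where there is nothing to do.
- The package answers only "where next?": when to stop, whether to add a
  location at all, and grid-invariant summary statistics are out of scope.
- Tessellation is recomputed from scratch each round (O(n²) half-plane
  clipping with pruning); fine for clinical grid sizes (~10 ms at n = 54),
  not tuned for hundreds of points.
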
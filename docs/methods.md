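# Methods

This note documents the models, conventions and numerical choices behind
`sparsesynergy`, and what the synthetic fixture does and does not establish
about real recordings.

## Phase model

The step cycle is delimited by successive onsets of a reference muscle and
normalized to unit length; events map to phases with phase 0 at the
reference onset and negative phases before it. Phase is treated as a
**linear** coordinate — no circular arithmetic — because the bursts this
analysis targets all fall within roughly (−0.5, 1.5) of a single reference
onset. A burst is assigned to the cycle whose half-open window
[start − 0.5·duration, end − 0.5·duration) contains its onset, so
pre-reference bursts receive onset phases in [−0.5, 0.5); a burst whose
offset extends past the next reference onset keeps an offset phase > 1
rather than being reassigned. Occurrence indices (e.g. `Bic(1)`, `Bic(2)`)
are assigned per cycle by onset order and reconciled across cycles by
matching deficient cycles to the median onsets of the modal-count cycles,
so a cycle missing its habitual first burst does not mislabel its lone
burst.

Burst magnitude is the sum of 1-ms envelope bins over the half-open
[onset, offset) window divided by the duration in ms — the mean in-burst
amplitude, deliberately invariant to duration changes so that magnitude and
duration effects can be separated.

## Adjacency criterion

Each burst is reduced to the ±1 SD rectangle around its centroid in the
(onset, offset) plane. The overlap margin between bursts *i* and *j* is

    q = max over the 16 vertex sign choices of
        (±σXᵢ, ±σYᵢ)·d̂ + (±σXⱼ, ±σYⱼ)·d̂  −  ‖d‖,

the projections of both rectangles onto the unit inter-centroid direction
d̂ minus the centroid distance. This closed form equals
(|σXᵢd̂x| + |σYᵢd̂y|) + (|σXⱼd̂x| + |σYⱼd̂y|) − ‖d‖ and is symmetric,
translation-invariant and homogeneous of degree 1 under joint scaling of
phases and SDs. We adopt this geometric (vertex-projection) reading rather
than a literal absolute-coordinate dot product, which would not be
translation-invariant; the test suite checks the closed form against
brute-force sign enumeration to 1e−12. Coincident centroids return +inf
(adjacent by convention). Clusters are the connected components of the
q > 0 graph, computed with union–find (path compression + weighted union)
and verified against an independent graph-traversal oracle.

## Protocol details and tie-breaks

All tie-breaks are fixed so the analysis is deterministic and invariant to
input row order:

- Outlier screen: iteratively remove the single trial with the largest
  per-coordinate deviation (onset or offset, in SDs recomputed each
  iteration) while it exceeds 2 SD; at most ceil(10% · n) removals; ties go
  to the lowest index; samples with n < 3 are left untouched. The screen is
  per coordinate; a bivariate variant was considered and rejected because
  the downstream model is built from marginal SDs anyway.
- Degenerate bursts (zero variance in either coordinate) get ρ := 0.
- Cluster numbering: ascending mean onset of member centroids; ties broken
  by the lexicographically first member label.
- Two-stage protocol: stage-2 bursts are processed in ascending mean-onset
  order; a candidate joins the cluster with the most q > 0 members (at
  least 2 for multi-member clusters, 1 for singletons), ties broken by
  centroid distance; bursts joining nothing are clustered among themselves.
- Constrained mode: known labels keep their reference cluster regardless of
  geometry; novel bursts go to the cluster with the most adjacent members,
  ties by nearest centroid; a novel burst adjacent to nothing goes to the
  nearest centroid with a warning.
- Cluster centroids used for inter-cluster distances are **unweighted**
  means of member burst centroids; the pooled statistics feeding the
  direct components are **trial-weighted** exact pooled moments. Both are
  exposed because the appropriate weighting for distance reporting is a
  genuinely open choice.

## Direct components and ellipses

A cluster with pooled stats (X, σX, Y, σY) yields a piecewise-Gaussian
profile peaking at Z = (X + Y)/2 with σ₁ = (Z − X)/3 + σX and
σ₂ = (Y − Z)/3 + σY, nominal support (X − 3σX, Y + 3σY). The evaluation
uses exp(−(t−Z)²/(2σ²)) — a proper Gaussian in phase units; a `literal`
mode with exp(−(t−Z)²/(2σ)) is provided for comparison since the
unsquared denominator appears in print, but the squared form is the default
on dimensional grounds. Tails are evaluated beyond the nominal support
(reported as metadata), not truncated. Output profiles are sampled on
1,000 uniform points over [−0.5, 1.5].

The 1 SD summary ellipse of the correlated bivariate-normal model is
u² + v² − 2uvρ = 1 − ρ² with u = (x−X)/σX, v = (y−Y)/σY. Boundary points
are generated by mapping a circle of radius √(1−ρ²) through the inverse
square root of the quadratic form; tangency to the ±1 SD rectangle at
(±1, ±ρ), (±ρ, ±1) is an algebraic identity checked to 1e−12. The area is
π σX σY √(1−ρ²).

## Statistics

One-way fixed-effects ANOVAs compare onset, offset, peak phase
((onset+offset)/2, computed per trial) and magnitude across conditions,
pooling the per-trial values of all member bursts of a synergy. F and p are
computed from explicit sums of squares with scipy's F distribution so that
degenerate inputs have defined limits (all values identical → F = 0,
p = 1; zero within-group variance with unequal means → p = 0); the tests
cross-check against `scipy.stats.f_oneway`. Pairwise comparisons use
Welch's t with Welch–Satterthwaite degrees of freedom (no equal-variance
assumption); raw p-values are reported, with an optional Bonferroni
helper. Magnitude percentages are 100 · mean(condition)/mean(control) per
burst; bursts inactive in the control have no defined percentage and are
excluded from the synergy-level direct-component scale (mean member
percentage / 100).

## Synthetic fixture

The packaged configuration plants 10 clusters over 27 bursts from 18
muscles (1–7 bursts per cluster), 8 clusters in swing and 2 in stance,
with 30–70 trials per burst. Centroids ascend from (−0.14, 0.00) to
(0.66, 0.92) with SDs of 0.02 cycle in swing and 0.03–0.04 in stance;
burst windows within a muscle never overlap, including across the cycle
boundary, so envelope traces can be synthesized for the control condition.
Per-muscle centroid offsets are uniform in a disk of radius 0.005 cycle.
The trail condition advances the three pre-swing clusters by 0.03–0.06
cycle and scales clusters 2–3 by gains 4.0 and 2.5; the lead condition
delays the two post-swing clusters by 0.04–0.05 cycle and scales clusters
4–5 by 2.0. Two supplementary bursts appear only in trail, near clusters 1
and 3. Magnitudes are lognormal around baseline × gain with CV 0.2
(positivity); trials are drawn from the correlated bivariate normal and the
rare draw violating offset > onset (≥ 5 SDs out) is redrawn. Everything is
bit-for-bit reproducible from (config, seed).

Adjacent-cluster separations (≈ 0.10–0.28 cycle) exceed the worst-case SD
projections (≈ 0.057 in swing) by ≥ 5 standard errors of the sampled
statistics, which is what makes exact recovery of the planted partition the
expected outcome and centroid jitter below 0.6 SD unable to alter the
composition. This mirrors the qualitative geometry of real locomotor data
but is deliberately cleaner: real bursts have asymmetric scatter, cycle-to-
cycle covariation between muscles, marking error in burst boundaries, and
borderline cluster separations. Passing recovery and jitter tests on the
fixture therefore validates the algorithmic chain, not the separability of
any particular real dataset. The jitter experiment displaces each burst
independently per repetition by a vector uniform in the disk of radius
0.6 · ‖(σX, σY)‖ (the norm is a design choice; the displacement bound is
stated in SD units without a defined norm in the source methods).

The default fixture contains no within-cluster differential phase shifts,
so its constrained and unconstrained solutions coincide apart from the
supplementary bursts; fragmentation of a synergy under a member-specific
shift (and its repair by the constrained mode) is exercised by a dedicated
test configuration where the geometry leaves room for a clean split.

## Problem sizes

Default analyses run on the 27-burst fixture (≈ 4,000 trial rows across
three conditions). The calibration simulations use 5,000 null replicates
and 1,000 effect replicates at n = 30 per group; recovery is checked over
100 generator seeds and jitter over 1,000 repetitions — sizes chosen so
binomial uncertainty on the reported rates is a few tenths of a percent.

## Known limitations

- Phase is linear; analyses of behaviors where bursts wrap the full cycle
  would need circular statistics.
- Burst boundaries are taken as given (manual marking upstream); no onset
  detection is provided.
- The Rosner-style screen uses a fixed 2 SD margin rather than
  significance-calibrated ESD critical values; with the 10% cap this trims
  a few percent of well-behaved Gaussian trials.
- The two-stage join rule and constrained novel-burst assignment depend on
  the processing order for pathological geometries; the documented
  ascending-onset order makes results reproducible but other orders could
  differ on borderline data.
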
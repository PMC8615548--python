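# Methods

`knotscope` implements the desk-side topology pipeline used to analyse
knotted proteins: given a Cα trace (or a trajectory of traces), decide
whether the chain is knotted, identify the knot type, locate the minimal
knotted core, and follow the core's termini through time to distinguish
untying by *loosening* (the termini move toward opposite chain ends) from
untying by *sliding* (a constant-size core translates off one end).  This is
the same analysis a KnotProt-style service performs on uploaded trajectories,
rebuilt as a local, seeded, testable library.

## Knot typing of an open chain

An open chain has no knot type until it is closed.  The pipeline:

1. **Stochastic closure.**  A point is drawn uniformly on a sphere of radius
   `radius_factor` × (maximum point-to-centroid distance), centred at the
   chain centroid, and both termini are joined to it by straight segments.
   One far point (rather than a two-point arc) is the simplest standard
   variant; the method flag leaves room for others.  A chain that is
   collinear within tolerance falls back to direct closure (joining last to
   first) with a warning, since a sphere around a degenerate chain is
   ill-defined.
2. **KMT reduction.**  The closed polygon is simplified by triangle
   elimination: sweep consecutive vertex triples in index order and delete
   the middle vertex whenever no non-adjacent segment intersects the closed
   triangle it spans; repeat until a sweep removes nothing.  Removal order
   can matter only if an intersection predicate errs, so predicates are
   conservative: touching within tolerance blocks removal.  Tolerances are
   relative to the curve's bounding-box extent (`eps_point = 1e-7` for
   coincidence/collinearity, `eps_det = 1e-9` for inside/outside tests); a
   near-degenerate triangle permits removal only when the middle vertex lies
   on the segment joining its neighbours.  The sweep kernel is numba-compiled
   — it executes millions of segment/triangle tests per trajectory.
3. **Generic projection.**  The reduced polygon (typically 6–10 vertices) is
   projected along a random direction.  Directions are rejected and redrawn
   (≤ 50 tries) on any near-degeneracy: coincident vertex images, a crossing
   near a vertex image, triple points, near-parallel overlapping segments, or
   ambiguous over/under depth.
4. **Alexander determinants, exactly.**  From the crossing diagram the
   Alexander matrix is built (rows = crossings, columns = arcs; the over-arc
   receives 1−t and the incoming/outgoing under-arcs −1 and t, swapped for
   negative crossings), one row and column are deleted, and the determinant
   is evaluated with exact integer arithmetic (fraction-free Bareiss) at
   t = −1 and t = −2.  `det1 = |Δ(−1)|` is the knot determinant.  Because the
   Alexander polynomial is defined only up to ±t^k, the magnitude at t = −2
   is ambiguous by a power of two; `det2` is therefore the odd part of the
   minor determinant's magnitude — the minimal positive integer invariant.
   Floating-point determinants are never used.
5. **Classification.**  The pair (det1, det2) is looked up in a table of
   prime knots through six crossings, shipped as package data with its
   provenance; anything else returns `unknown`.  Two evaluation points are
   needed because det1 alone cannot separate the figure-eight knot (5) from
   the (2,5) torus knot (5); beyond six crossings labels are refused rather
   than risked.  The Alexander polynomial is blind to chirality, so mirror
   images share a label (tested, documented).

Typing a chain = tallying labels over `n_closures` independent closures
(default 100).  The chain's type is the dominant label under majority rule
(frequency > 0.5); ties break toward fewer crossings.  The spectrum is
invariant under rigid motion up to binomial sampling error, and a closure
sphere at 3× the chain extent already gives the same spectra as 10×
(both tested).

## Knotted-core localization

The core is the minimal subchain retaining the chain's dominant type.  By
default each boundary is trimmed **independently against the otherwise-
complete chain**: advance the start while the subchain keeps the dominant
type at majority frequency, and likewise retract the end.  Sequential
trimming (start-then-end, exposed via `trim_order`) compounds errors when
the first trim stops inside the closure-ambiguous zone — the remaining
subchain is marginal and the second trim stalls — which is why independent
trimming is the default.  Boundary search uses galloping (exponential probe
+ bisection, ~2 log L typings per side) under the assumption that removing
more of an unknotted tail never restores the knot; a strictly linear scan is
available and agrees on solid fixtures (tested).

Validation mode: the knotting **fingerprint** types every subchain [i..j] on
a stride grid.  Its core estimate takes the connected region of knotted
cells containing the widest knotted subchain, erodes one-cell protrusions
(a cell carried by one lucky closure ensemble must not set a boundary), and
reads the outermost knotted row/column — the same "last residue whose
removal loses the type" estimand the greedy search trims toward.  On tight
open-trefoil fixtures the two agree within 2 residues.

**Intrinsic resolution.**  Stochastic closure gives smooth knotted arcs a
soft essentiality edge: the probability that a one-side-trimmed subchain
still closes to a trefoil decays over ~2–4 residues rather than stepping.
Boundaries on harmonic (torus-parametrized) arcs therefore land a few
residues inside the geometric span, while tight knotted blocks give
±1-residue boundaries.  Tests and acceptance checks are calibrated to the
estimand (exhaustive-fingerprint agreement, tail exclusion), not to the
parametric span.

## Trajectory tracking and untying classification

`track_knot` runs `find_core` per frame with an independent RNG substream
(seed = base + frame index), so any frame is reproducible in isolation.
Tracking warm-starts the trim near the previous frame's core (±4 residues),
verified and with full-search fallback — per-frame core motion in these
trajectories is ≤ ~2 residues, and the warm start saves most subchain
typings.

`classify_untie` works on the per-frame records: the untie frame is the
first frame of a terminal unknotted run of ≥ K frames (K = 5); the mode is
read from the last W knotted frames (W = 20), median-smoothed at both window
ends to resist single-frame closure noise, with a δ = 3-residue materiality
threshold: loosening if the start moved ≥ δ N-ward *and* the end ≥ δ C-ward;
sliding toward a terminus if the mid-position moved ≥ δ that way with
|Δsize| < δ; otherwise maintained — or loosening-by-default (flagged) when
the chain untied without a clear signature.

## Structural observables

Native contacts: residue pairs with minimum heavy-atom distance < 4.5 Å and
sequence separation ≥ 4 (common practice; the criterion sits in config).  A
Cα-only trace falls back to Cα distances with an 8 Å cutoff.  Q(t) is the
fraction of a contact group's pairs closer than 1.2× the cutoff in frame t,
so the reference frame scores exactly 1.  Contact maps store minimum
inter-residue distances.  The three-residue backbone angle is the planar
angle at the middle Cα — the reported "turn rigidity" quantity spans a
90–120° range, consistent with a planar angle, and no fourth atom for a
proper dihedral is specified anywhere, so the angle interpretation is
implemented and the ambiguity recorded here.  H-bonds are counted by the
hydrogen-free geometric criterion (N/O–N/O pairs of different residues
within 3.5 Å), which needs all-atom input.

## Synthetic data: what it emulates, and what it does not

All fixtures are polygonal Cα-like chains, one point per residue at a 3.8 Å
virtual bond, fully determined by their RNG seed:

- **Reference curves** from standard parametrizations: (2,q) torus knots,
  the harmonic figure-eight, circles, random walks.
- **Open knots with tails**: a closed curve opened by removing `gap`
  vertices, with straight tails extending away from the centroid.  Tails
  keep the termini exposed, which keeps subchain typing decisive.
- **Loosening trajectories**: knotted frames are trefoil subarcs whose
  residue span grows at the expense of both tails (the loosening signature);
  frames from the untie frame on use a simple planar curve.  Planarity makes
  the unknotted side *certain by construction*, and the knotted side is a
  deeply knotted family (typing dominance ~0.95).  The price is that the
  conformation jumps at the untie event rather than passing through a
  continuous pull-through; the classifier consumes only per-frame records,
  so the discontinuity is immaterial to what is being tested.  (A continuous
  retraction along the thread's own path was prototyped and abandoned: the
  frame at which such a family unties is itself implementation-defined,
  which would have made the ground truth circular.)
- **Sliding trajectories**: a rigid 24-residue trefoil block embedded in a
  straight chain, translated one residue per frame with size fixed — the
  phenomenology of a knot pushed along an unfolding backbone, ~20 residues
  of drift at the default length.  These frames *are* continuous rigid
  motions.
- **Two-domain fixture**: two rigid helical blocks, one translated on a
  schedule; planted native contacts are all inter-block pairs within cutoff
  at frame 0.  A parallel-strand "ladder" variant breaks exactly half its
  contacts for the Q = 0.5 check.
- **Synthetic YbeA-like model** (`synthetic_ybea_model`): a 155-residue
  stand-in for the trefoil-knotted methyltransferase — trefoil arc planted
  over residues 70–120 (the loop-plus-threading region), 69-residue
  unknotted N-arm, 35-residue straight C-tail.  It reproduces the protein's
  knot *architecture* (shallow trefoil, core ending ~35 residues before the
  C-terminus); it is not the crystal structure, and the detected core sits a
  few residues inside the planted span for the resolution reasons above
  (detected onset ≈ 77, C-tail ≈ 42).

None of the fixtures have excluded volume, side chains, or physics; passing
tests show the *topology pipeline* is correct and its estimators calibrated,
not that any molecular-dynamics observation would be reproduced.

## Problem sizes and defaults

Chosen so the whole validation battery runs in minutes on one core: typing
validation 4 curve types × 20 rigid motions × 2 noise levels; KMT invariance
200 randomized fixtures; core recovery on 52–60-residue chains with stride-1
fingerprints at 50 closures; untying recovery on 20 loosening (22–30 frames)
plus 20 sliding (21 frames) trajectories of 60 residues at 25 closures per
typing; trajectory jitter σ = 0.19 Å (0.05 bond lengths).  Default closure
count for single-chain work stays at 100.

## Known limitations

- Knot types beyond six crossings report `unknown`; composite knots and
  slipknots are out of scope, as are links.
- Chirality is invisible to the Alexander polynomial; 3_1 and its mirror
  share a label.
- Dominance thresholds near 0.5 make boundary residues of smooth knotted
  arcs intrinsically fuzzy (±2–4 residues at 25–100 closures).
- The XYZ dialect and single-chain PDB reading cover the fixture formats and
  ordinary crystal structures; mmCIF and compressed trajectory formats are
  not supported.
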
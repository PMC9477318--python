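# Methods

This note documents the models, numerical choices and defaults behind
`whiskmap`, and what the synthetic data used by the tests does and does not
establish about real whisker data.

## Coordinate conventions and geometry

Whisker-centered coordinates place the origin at the basepoint with the
x-axis collinear with the proximal region of the whisker (operationalized as
the chord from the base to the node at 10% of arc length), the best-fit
plane of the proximal 70% of the arc rotated onto the x-y plane, and the
intrinsic curvature pointing the tip toward +y. Frame alignment is
deterministic, idempotent, and invariant to rigid motions of the input
(asserted to 1e-6 mm in tests). A contact point is expressed as
(r, θ, φ): Euclidean distance from the origin, azimuth from the x-axis, and
elevation from the x-y plane. Angles are degrees at all file and API
boundaries and radians internally; signal directions (F_D, M_D) are radians
in [0, 2π).

The synthetic "γ-like" whisker is a 20 mm arc with an in-plane quadratic
profile (y = 0.02·x², a mid-range curvature coefficient for rat macro-
vibrissae) and a cubic out-of-plane displacement confined to the distal 30%
of the arc, reaching 12% of the arc length at the tip — enough out-of-plane
curvature to make the twisting moment M_x informative, while the proximal
70% stays near-planar, as in real whiskers whose distal segment leaves the
plane of the proximal shaft. Discretization is 100 nodes at uniform
arc-length spacing (the resampler iterates to a fixed point so the polyline
is uniform in its own chord metric, making save/load round trips exact).
Linear taper runs from a 100 μm base radius to 100/15 ≈ 6.67 μm at the tip.
Material defaults: E = 3 GPa, ν = 0.38.

## The discrete elastica and the contact solver

The rod is a chain of rigid links joined by elastic joints: bending
stiffness EI(s) with I = πr(s)⁴/4, torsional stiffness GJ with
G = E/(2(1+ν)) and J = 2I (so GJ = EI/(1+ν)). Reference joint rotations are
built from parallel-transported frames of the undeflected shape (zero
intrinsic twist); joint compliances carry trapezoidal weights (half weight
at the clamp) so the small-deflection limit reproduces Euler–Bernoulli
integrals to O(ds²) — the closed-form tip deflection of a uniform cylinder
is matched to 0.01% at 100 nodes.

Equilibrium under a point load F applied at arc s_c requires each joint
rotation to equal its reference plus compliance × the internal moment
(p_c − p_i) × F expressed in the local frame; this fixed point is relaxed by
damped successive substitution (adaptive mixing 0.01–1.0, tolerance 1e-10
rad). The frictionless contact problem — find (F, s_c) such that the
material point at s_c reaches the target and F ⊥ the local tangent — is a
damped Newton iteration on the 4-vector (F, s_c) with finite-difference
Jacobian, backtracking line search, and tolerances of 1e-6 mm on position
and 1e-8 on the normalized tangential force fraction. Internal units are
mm / μN / μN·mm with E in μN/mm², which keeps typical magnitudes within a
few orders of unity.

Failure of this iteration (line-search stall, force blow-up past 1 N, or
the contact arc leaving the rod) is reported as *slip* and the grid point
discarded, mirroring how slipping contacts are treated when the reachable
space is generated. On the γ-like whisker the converged set forms a single
connected cloud around the whisker out to total deflections of roughly
40–50°; the slip fold is reached while the deflected tangent at the contact
crosses the plane perpendicular to the x-axis, so only a thin shell of
"large deflection" contacts (deflected tangent_x < 0) converges. Base loads
are the loads transmitted through the base cross-section (the force and
moment the whisker exerts on the follicle): F_base = F_applied,
M_base = p_contact × F_applied. With this sign convention the axial force
is positive when the contact pulls the whisker out of the follicle, which
happens in a thin region of distal, small-deflection contacts on the
straightening side of the curved whisker.

## Mapping tables, exclusion and inversion

Grids are Cartesian products with inclusive endpoints; the full grid is
r = 6–20 mm × θ = −65..65° × φ = −60..60° at 1 mm / 1° / 1° (237,765
points), the desk-scale default is 2 mm / 3° / 3° (14,432 points, of which
≈2,900 converge on the γ-like whisker). Contact points closer to the
whisker than s_closest·tan(2°) are flagged as small-deflection exclusions:
lookup resolution in r collapses there because near-zero signals move the
radial estimate by many millimetres.

Inversion embeds a signal triplet with magnitudes z-scored over the table
and directions as (cos, sin) pairs (comparable variance to a z-scored
magnitude, no 0/2π seam), then reads (r, θ, φ) by inverse-distance
weighting over the k = 8 nearest retained records; an exact signal match
short-circuits to that record (ties to the smallest r), and queries farther
than 3× the table's median nearest-neighbour spacing are flagged as
extrapolations (the estimate is still returned).

Region labels: a record is *large deflection* when the deflected tangent at
the contact has negative x-component (the segment has rotated past parallel
to the y-z plane — beyond the tube where F_T passes through its minimum and
F_D rotates rapidly); otherwise azimuth sign splits *concave forward*
(θ ≤ 0, deflection against the intrinsic curvature) from *concave backward*
(θ > 0).

## Uniqueness testing

Each of the 20 triplets is tested by two independent criteria, both of
which must pass, unanimously over three seeds, for a verdict of *unique*:

1. **Function-approximator solvability.** A feed-forward network (two tanh
   layers of 64 units, adam, early stopping) is fit from the embedded
   triplet to z-scored (r, θ, φ) on a 75% split; held-out median absolute
   errors must fall below 1 mm in r and 2° in θ and φ (defaults,
   config-exposed and echoed in every report). A many-to-one mapping forces
   the network to average distinct branches, inflating these errors.
2. **Geometric overlap scan.** All pairs of retained records within
   ε_sig = 0.2× the median nearest-neighbour spacing in standardized signal
   space are enumerated exhaustively (KD-tree range query); any pair whose
   contact points are more than ε_cp = 5 mm apart is a counterexample, and
   the count must be zero. The 0.2 factor restricts the scan to
   *sub-resolution* coincidences: measured pair-distance spectra show true
   mapping folds collide at essentially zero signal distance, while pairs
   reflecting the known near-whisker radial resolution limit (a
   conditioning problem, not a folding of the mapping) sit above ≈0.25× the
   median spacing. The calibration anchors are the clear cases: an
   untapered (cylindrical) whisker must fail for (F_x, M_B, M_D), a planar
   whisker with in-plane contacts must fail for any triplet containing
   M_x (identically zero there), and the tapered curved whisker must pass
   for (F_x, M_B, M_D). All three hold with these defaults.

Disagreement between seeds, or an approximator that fails to converge, is
reported as *inconclusive*, never as unique. Region-conditioned verdicts
(ELD = excluding large deflections, CF/CB = one curvature side only, and
their combinations) reuse the same procedure on the filtered table.

On the synthetic γ-like whisker, six triplets are unique over the full
non-excluded space — F_x-F_T-F_D, F_x-F_T-M_D, F_x-F_D-M_B, F_x-M_B-M_D,
F_T-F_D-M_B and F_T-M_B-M_D; every one combines at least one magnitude with
at least one direction signal. Which triplets are unique is a property of
the whisker's intrinsic shape (taper and curvature), so this set is
expected to shift for whiskers of different geometry; the acceptance test
that pins the count to a specific tracked whisker's outcome is accordingly
strict.

## Sensitivity analysis

The 3×3 Jacobian of (r, θ, φ) with respect to (M_D, M_B, F_x) is evaluated
by central differences of a scattered-data interpolant at every retained
table record inside the analysis envelope (18 interpolations per probe).
Steps are 0.05% of each variable's envelope range; the envelope defaults to
the span of the synthetic behavioral trial (falling back to the full table
when the trial covers too few records at coarse grids). M_D is shifted onto
a continuous branch about its circular mean before interpolation.
Interpolation is linear over a Delaunay triangulation; probes whose ± step
leaves the convex hull are flagged invalid rather than extrapolated, and
the method is recorded in the output metadata. For presentation, each
element is trimmed to its central 99% interval and binned 50×50 over
(variable × value); display weight is bin count over the maximum count,
floored at 0.05 for bins under 5% of the maximum. Bookkeeping guarantees
valid + invalid = probes and binned = valid − trimmed per element.

The conditioning claim checked by the tests is that the interquartile range
of each element in the M_B column (against |M_B|) and the F_x column
(against |F_x|) contracts from the bottom to the top quartile of the signal
magnitude — estimates are most certain where the signals are large. The
M_D-column angular elements do not contract with moment magnitude (their
spread is organized by M_D phase, not by signal size) and are not asserted.

## The synthetic whisking trial

The generator emulates the structure, not the particulars, of a
body-restrained rat whisking against a vertical 2.7 mm peg at 1 kHz frame
resolution: three 6 Hz whisk cycles (raised-cosine protraction, amplitude
25°), a slow ±6° elevation oscillation at 1.5 Hz that spreads successive
contacts along the peg's vertical axis, a fixed basepoint with 0.06 mm
Gaussian jitter (≈ one 58 μm camera pixel) and 0.5° angle jitter, and
zero-phase 4th-order Butterworth smoothing of basepoint and emergence
angles at 85 Hz (measured response: <1 dB to 60 Hz, >20 dB at 200 Hz).

Contact geometry uses a tangency model: at each frame where the rigid posed
whisker would penetrate the peg, the whisker is rotated back about the
vertical axis through the basepoint by the azimuthal overshoot δ to the
grazing configuration; the grazing point projected onto the cylinder
surface is the ground-truth contact (asserted to lie on the surface), and δ
is the deflection the elastica solver reproduces when driven to that
contact point. A side state machine flips caudal→rostral (and back) when δ
exceeds a 12° slip cap, so each cycle produces a back-surface episode
during protraction, a slip past the peg, and a front-surface episode during
retraction — the M_D series flips by ≈180° between the two surfaces.

What the synthetic trial does **not** emulate: whisker roll/torsion during
whisking (contacts therefore stay near the whisker's own plane, and the
elevation coordinate φ of the contacts spans only a few degrees), head
motion, collision dynamics and vibrations, friction, tissue compliance at
the follicle, and multi-point or sliding contact. Passing tests on this
generator demonstrate that the pipeline is self-consistent — forward
mechanics, inversion and frame bookkeeping close the loop to sub-millimetre
median error — not that tracked video of a real whisker would achieve the
same accuracy.

## Reconstruction error decomposition

Per retained contact frame, the estimate−truth error vector in the whisker
frame is split into a radial component (along the true contact direction
from the base) and an angular component (perpendicular to it), both in mm.
With the default reduced grid the radial grid pitch (2 mm) is coarser than
the angular pitch (3° ≈ 0.6 mm at 11 mm), and radial information degrades
as signals shrink, so the median |radial| error exceeds the median angular
error — the same asymmetry that makes the reconstructed peg slightly
smeared in depth while its front/back surfaces resolve cleanly.

## Determinism and seeds

The elastica solver and sweeps are deterministic. Randomness enters only
through the trial generator's jitter, the uniqueness train/test splits and
network initializations, and round-trip sampling in tests; each consumer
derives a child seed from the global seed by hashing the stage name, so
stages can be rerun independently. All seeds stay below 2³¹.

## Known limitations

- The slip fold limits converged contacts to total deflections ≲50°, so the
  large-deflection class is a thin shell; region-conditioned uniqueness on
  ELD/CF/CB subsets is implemented but the ld population is small.
- Natural-neighbour interpolation is not available in the dependency stack;
  linear simplex interpolation with an invalid-probe guard is used instead
  and recorded in the sensitivity metadata.
- Uniqueness thresholds are calibrated on the clear-case anchors above;
  verdicts for triplets near threshold can legitimately differ from those
  of other implementations with different (unpublished) thresholds.
- The contact model is a single frictionless point load at the material
  point nearest the target, accepting a discretization error up to half a
  link length (≈0.1 mm at 100 nodes).
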
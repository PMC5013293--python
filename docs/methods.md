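# Methods

## The measurement problem

A protofilament-forming protein dimer simulated in solution drifts away
from its initial, crystallographically straight arrangement. Two numbers
summarize where it goes: the *twist* — how far one subunit has rotated
relative to its neighbour about the filament axis — and the *bend* — how
far the second subunit has tipped off that axis. Extrapolating the
instantaneous subunit-to-subunit map into a long filament turns those
per-interface numbers into filament architecture: a twist of θ per subunit
closes a full helical turn in 360/|θ| subunits, so ~25.7° per subunit gives
a one-turn, 14-subunit helix. In parallel, the identity of the residue
pairs that hold the interface together — and when each pair engages or
disengages — characterizes *how* the interface rearranges as twist
develops.

## Twist and bend

For each frame the package computes the mass-unweighted covariance of each
subunit's Cα coordinates and takes its eigenvectors as the subunit's
principal axes (e₁ = largest variance). With **u** the unit vector from
subunit A's centroid to subunit B's:

* twist = signed angle, right-hand rule about **u**, between the
  projections of the two e₁ axes onto the plane perpendicular to **u**;
* bend = the swing angle of the swing–twist decomposition about **u** of
  the relative subunit rotation (the Kabsch superposition of A's matched
  atoms onto B's).

Twist is referenced to the first frame — trajectories start from a
straight, untwisted state, so frame 0 reads zero — and an `absolute` mode
skips the referencing for constructed inputs that begin already twisted.
Principal axes carry an intrinsic sign ambiguity; it is resolved by
temporal continuity (each frame's axes are flipped to maximize the dot
product with the previous frame's), and the assembled series is unwrapped
so no frame-to-frame step exceeds 180°. If a subunit's e₁ falls within 1°
of **u** the projection is ill-conditioned and the frame's twist is
reported as missing, with a warning.

The swing–twist twist component is computed alongside as an internal
cross-check: for pure axial rotations the two definitions agree to
numerical precision, and they stay within ~1.5° of each other for bends up
to 20° (bound fixed by Monte-Carlo during development). The projected-axis
definition is the headline metric; the bend definition (swing component)
is a package design choice, since "bent but untwisted" admits several
formalizations, and is flagged as such here.

Atom selection defaults to Cα only — insensitive to side-chain motion and
standard in filament-geometry work; a backbone or all-atom selection is
available through the `selection` argument.

## Screw decomposition and filament building

The interface transform T (rotation R, translation t) is reduced to screw
form: angle from the axis–angle form of R; rise = t·axis; axis point from
the minimum-norm solution of (I−R)p = t<sub>⊥</sub>, which lies in the
plane perpendicular to the axis. The axis is oriented so the rise is
non-negative and the angle signed accordingly. Rotations below 0.01° are
reported as angle 0 with the axis along the translation (a pure rise);
below that the transform is flagged degenerate. Compose∘decompose
round-trips to 1e-8 for generic transforms. Filament models apply T
repeatedly from subunit A (or from B with T⁻¹ via `anchor="b"` — which
subunit anchors a rendering is a free choice); a generator with both
rotation < 0.01° and rise < 0.01 Å is rejected, since the subunits would
superimpose. A clash screen reports non-adjacent subunit pairs with any
interatomic distance below 2 Å; adjacent subunits are exempt because they
share the physical interface.

## Interface contacts and temporal classification

A residue pair (one residue per subunit) is in contact when the minimum
distance over its heavy atoms is strictly below 5 Å. Heavy atoms are the
default because hydrogen positions in MD are slaved to their heavy
neighbours and 5 Å residue-contact censuses conventionally use heavy atoms;
`heavy_only=False` includes hydrogens. Contact detection uses a k-d tree
and is verified against an O(N²) brute-force reference.

Occupancy is the fraction of frames within a half-open [t, t+12.5 ns)
block in which the pair is in contact; a pair is *present* in a block when
occupancy ≥ 0.5 (the published block indicators are binary without a
stated binarization; majority-of-frames is the package's reading, and the
threshold is configurable). A trailing partial block shorter than half a
block is dropped with a warning. Comparing a WT-like and a variant-like
run over the union of their pairs (keyed by residue numbers, since the
mutated position changes identity but not position):

* **nontwisted-specific**: present in ≥1 WT block fully inside the first
  100 ns, in no WT block starting at/after 150 ns, and in no variant block;
* **twisted-general**: present in every variant block and in every WT
  block starting at/after 150 ns;
* **variant-specific**: present in ≥1 variant block and in no WT block;
* anything else: unclassified.

Given at least one variant block and one late WT block the three rules are
mutually exclusive; the test suite proves label correctness exhaustively
over all 2⁶ presence patterns on a three-block toy.

Salt-bridge-style traces report the per-frame distance between the
mass-weighted centers of two named residues (heavy atoms by default). The
package tracks distances for user-named pairs only; it does not decide
chemically what constitutes a salt bridge.

## Synthetic trajectories

The generator emulates exactly the features the estimators measure, and
nothing more. Subunit A is a rigid pseudo-protomer: 316 residues (the
modeled core of an FtsZ subunit), three atoms per residue, whose Cα cloud
is rotated and rescaled so its *sample* covariance has exactly the planted
principal axes (x, y, z) and spreads (10, 5, 2.5 Å — consecutive variance
ratios of 4). Frame k places subunit B as a copy rotated by θ(t_k) about
+z, swung by bend(t_k) about +y, and raised 44 Å along +z (the axial
subunit spacing), then adds i.i.d. isotropic Gaussian noise (default
σ = 0.5 Å) to every atom. Twist/bend profiles are constant, linear (a ramp
reaching θ_max at t₀, a package definition) or logistic
θ_max/(1+exp(−(t−t₀)/τ)).

Contact schedules are planted through designated residues that carry
side-chain-style atoms only (no Cα): their atoms are placed *exactly* at
the scheduled on/off distances (default 4 Å / 8 Å, straddling the 5 Å
cutoff) at lateral sites well clear of both subunit bodies, and are exempt
from noise. Two consequences, both deliberate: planted contact schedules
are recoverable at any noise level, and relocating marker residues never
perturbs the Cα-based geometry estimators — at σ = 0 every estimator sits
on the planted truth to numerical precision. The Arg67/Asp97 stand-ins
keep their namesake residue numbers and names.

Two presets emulate the two simulated conditions at the published scale
(300 ns, sampled as 240 frames at 1.25 ns): `wt-like` (logistic twist with
midpoint 180 ns — twist arrives late; an early-only pair, a late-arriving
shared pair, an always-on pair, and a 67–97 bridge connected for 100 ns,
briefly reformed at 110–120 ns, then broken) and `variant-like` (midpoint
25 ns — twisted within the first 50 ns; the shared pair always on, a
variant-only pair from 50 ns, the bridge broken after 15 ns). These are
presets for exercising the pipeline, not claims about any particular
simulation.

What the generator does *not* emulate: correlated (low-frequency
collective) MD noise, internal subunit flexibility, coupling between bend
and twist, or any force-field physics. Passing recovery tests therefore
demonstrate estimator correctness under a stationary perturbation model,
not performance on real trajectories, where slower collective motions
would inflate the effective noise.

Sizes used in the shipped tests and acceptance script (240-frame series,
5–20 Monte-Carlo seeds, 100-seed power runs) were chosen so the whole
suite completes in a few minutes on one core while leaving the planted
effects far above the estimator noise floor.

## Morphometrics

Aspect ratio is max/min of the two cell axes, so a swapped length/width
pair cannot yield a ratio below 1; from a pixel mask it is the major/minor
axis ratio of the ellipse with the same second central moments
(scikit-image regionprops; pixel size cancels). The Mann–Whitney U uses
midranks; the exact two-sided p enumerates all C(n+m, n) labelings when
n+m ≤ 16 (≤ 12,870 arrangements) and the pooled data are tie-free — exact
enumeration over tied data would require permuting values rather than
ranks and is out of scope, so ties fall back to the normal approximation
with a warning. The approximation uses the tie-corrected variance and a
0.5 continuity correction; at the n+m = 16 boundary it stays within ~0.011
of the exact p (Monte-Carlo, 2,000 draws). Identical pooled samples are
degenerate: p = 1, flagged.

The two-condition generator draws log-normal ratios (default medians
1.05 vs 1.5, geometric SDs 1.1 vs 1.3, n = 50/group — a round-cell
condition against an elongating one). Draws below 1 are folded (r → 1/r),
matching the max/min canonicalization of measured ratios; a geometric SD
of exactly 1 degenerates to the median, as the tests require.

## Numerical conventions and edge cases

Angles in degrees, distances in Å, times in ns, masses in Da throughout.
Rotations are validated orthonormal with det +1 to 1e-8 everywhere.
Residue numbering follows the author/PDB `resseq` field (1-based), because
interface residues are named that way (Arg67, Asp97, Gly193). Trajectory
time is a user input (`dt_ns`, default 0.5 ns/frame) since PDB carries no
time axis. First altlocs are kept and duplicates dropped with a warning;
insertion-code duplicates likewise — MD-derived structures carry neither.
Near-degenerate covariance eigenvalues (relative gap < 1e-6) flag the
principal frame as axis-ambiguous rather than failing. PDB output writes
coordinates to 3 decimals; round-trips preserve coordinates to that
precision and residue ladders exactly.

## Known limitations

* The twist definition operationalizes a figure-style "angle between
  principal axes seen down the filament axis"; other conventions (e.g.
  smoothing across frames, absolute crystallographic reference) would give
  systematically similar but not identical series on real data.
* Exact Mann–Whitney refuses ties instead of enumerating value
  permutations.
* Filament models are rigid extrapolations: no relaxation, no lateral
  filament–filament contacts.
* Binary trajectory formats (DCD/XTC) and mmCIF are out of scope; only
  fixed-column PDB dialects are read.
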
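# Methods

## Model and conventions

`rotascape` analyses the relative orientation of two rigid bodies of one
complex, each refined separately from the same particle stack. Per body,
the refinement assigns ZYZ Euler angles `(rot, tilt, psi)` in degrees; the
corresponding matrix is `R = Rz(psi) Ry(tilt) Rz(rot)` under the
right-handed, counter-clockwise-positive convention of the refinement
package whose STAR files are consumed. A worked anchor for detecting any
convention mismatch: `(rot, tilt, psi) = (90, 0, 0)` maps the unit x axis
onto the unit y axis.

The relative orientation is `R_rel = R_modᵀ R_cond`: the **modifying wing
is the fixed reference frame** and the condensing wing moves in it. The
choice of which body supplies the inverse is a convention, not a physical
fact; swapping the roles transposes `R_rel` (equivalently negates the
z–y–x angles in reversed composition order), and the pairing API accepts
the tables in either order, so the flip is one argument swap.

`R_rel` is decomposed as intrinsic z–y–x Tait–Bryan angles,
`R_rel = Rz(α) Ry(β) Rx(γ)`, with canonical ranges α, γ ∈ (−180°, 180°]
and β ∈ [−90°, 90°]. Closed-form extraction: β = arcsin(−R₃₁),
α = atan2(R₂₁, R₁₁), γ = atan2(R₃₂, R₃₃). At gimbal lock (|β| = 90° within
1e−7°) only α∓γ is determined; we set γ := 0 and let α absorb the free
angle, so rebuilding the matrix from the reported angles always reproduces
the input within 1e−9 Frobenius. Double-precision matrix products are
accurate to ~1e−13, so the 1e−9 orthonormality and round-trip tolerances
are loose by four orders of magnitude and never trip on valid input.

### C2 handling

Symmetry expansion duplicates each particle with the point-group operator
applied per body, so the relative rotation of one physical particle is only
defined up to `S_modᵀ R_rel S_cond`, with S ∈ {I, C2(axis)}. Both bodies'
C2 axes default to z of their reference maps and are overridable. The
canonical representative of the ≤4-member equivalence class is the
lexicographic minimum of (|β|, |α|, |γ|), with the signed triple
(β, α, γ) as a total tie-break; this makes canonicalization idempotent and
invariant to which expansion copy is supplied. The canonical choice is a
package convention (any deterministic rule works); it matters only that
both copies of a particle collapse to the same point.

## Landscape

Orientations are histogrammed on a regular 3D grid covering the canonical
ranges. Defaults: **bin width 2°**, chosen so the ~14° selection radii used
for subset reconstruction span seven bins, and **smoothing σ = 1 bin** of
Gaussian filtering. α and γ are periodic (the filter and all neighbour
operations wrap across ±180°); β is clamped — it cannot leave [−90°, 90°]
by construction. The smoothed density is normalized to sum 1 so landscapes
of different particle counts (e.g. per-substate landscapes) are directly
comparable. `local_density` interpolates trilinearly with the same
wrap/clamp topology.

Hotspot detection is a package-defined operation (favoured orientations are
usually reported simply as coordinates): strict local maxima of the density
(26-neighbourhood, wrapped) at or above a percentile — default 97.5 — of
the *nonzero*-density bins, greedily pruned so no two reported centers are
within `min_separation` (default 10°, wrapped Euclidean), sorted by
descending density. Percentile thresholding over nonzero bins makes the
threshold independent of how much of the grid is empty, but when a scene
contains a broad diffuse background most nonzero bins are single-count
tail bins and the 97.5th percentile sits near the noise floor; genuine
modes still rank first by density, and a higher percentile (99.9) or a
larger `min_separation` suppresses the tail maxima. A perfectly flat
density has no strict maximum and yields an empty list.

## Selection and export

Selection uses the Euclidean metric in (Δα, Δβ, Δγ) degrees with wrap on
α and γ — the same coordinate space the landscape is built in — with the
boundary included (≤ r). A geodesic SO(3) metric (rotation angle of
`R_centerᵀ R_i`) is available behind `metric="geodesic"` but is not the
default, to keep the selection geometry identical to the plotted
coordinates. Exports copy the condensing-body angles verbatim (6-decimal
STAR formatting) and preserve passthrough columns and any optics block.
Selections below 200 particles are flagged: around 200 particles suffice
for a ~20 Å reconstruction with a well-defined inter-body orientation, and
below that reconstructions become unreliable.

## Substate recombination

Condensing-wing monomer labels come from upstream focused classification
(five functional groups: ACP–KS, ACP–MAT, ACP-in-transition, no-ACP,
dynamic-MAT); modifying-wing labels are Ψ-resolved / Ψ-unresolved. Dimeric
condensing pairs are counted **unordered** (15 for five groups) while
modifying combinations remain **sided** (4: both / side-A-only /
side-B-only / neither) — an asymmetry implemented as specified, with
`collapse_sides=True` for the symmetric 3-combination alternative. Side A
is the copy whose condensing label sorts first; when the two condensing
labels are equal the copy with the resolved Ψ-domain is taken as side A,
which keeps assignment total, deterministic, and invariant under swapping
the expansion copies. Per-substate landscapes filter dimers by assigned
substate and use expansion copy 0 (with canonicalization the choice of
copy is immaterial); the per-substate particle counts partition the
labelled total exactly.

## Tether reach

The carrier domain is anchored near a known residue of the static wing
(default selector semantics: Cα of the anchor residue, catalytic side-chain
atom of each site — both configurable as `chain/resnum/atom`). The reach
budget defaults to **80 Å**, an estimate of the maximum stretch of the
linker plus carrier domain plus phosphopantetheine arm; it is a
configuration value, never recomputed. The scan rotates each site by α
about the user-supplied pivot axis through the pivot point (the pivot is
not derivable from a single structure and must be given; it can be
measured from the two aligned wing models) and reports the
anchor-to-site distance profile, per-site maximal contiguous accessible
α-intervals (merged across the ±180° seam, so a wrapped interval is
reported with lo > hi), and their intersection. Only α is scanned by
default (β = γ = 0), matching how distance-vs-swivel profiles are plotted;
on cylindrical toy geometry the profile reduces to the law of cosines,
which the tests use as the closed-form oracle.

## Synthetic scenes

The generator emulates two focused refinements of one stack at the
metadata level. Body-1 poses are uniform over SO(3) (normalized random
quaternions); each particle draws a mixture component by weight and a
relative orientation from a **per-axis wrapped Gaussian** around the
component center — matching the coordinate space the landscape lives in; a
matrix-Fisher sampler would be the rotation-group-native alternative but
is out of scope. Per-body assignment error is a small random rotation
(uniform axis, half-normal angle of scale `noise_sigma`, default 1°)
composed independently onto each body. C2 expansion emits each particle
twice with the 180°-about-z operator composed per body, and per-monomer
class labels are written from the component's label pairs. Identical seeds
give byte-identical STAR output.

The default scene places tight modes (σ = 5°) at (13°, 0°, 14°) and
(−3°, −8°, −8°) — the two favoured coordinates used for hotspot
reconstructions — plus a broad (σ = 40°) background of unengaged
particles. The recovery and acceptance checks use a well-separated
three-mode scene (third mode at (−40°, 0°, 12°), weights 0.5/0.3/0.2,
n = 50,000, σ = 5°, noise 1°): mode separations of ≥28° against 5°
component widths make nearest-center weight estimation essentially exact,
which is what lets the 0.03 weight tolerance be meaningful rather than
generous. Problem sizes (50,000 particles for recovery, 20,000 for the
variance comparison, 10,000 matrices for round trips) keep the full suite
under half a minute while leaving Monte-Carlo errors an order of magnitude
below the asserted tolerances.

What the scenes do **not** model: image-space effects (CTF, noise,
alignment bias correlated with orientation), non-isotropic or correlated
angular errors between the two refinements, classification label noise,
and any coupling between viewing direction and relative orientation.
Passing recovery tests therefore demonstrates the correctness of the
geometry, binning, detection and bookkeeping — not robustness to
refinement pathologies of real data.

## Degenerate inputs and numerical choices

- Orientations exactly on the ±180° seam bin into the last (right-closed)
  periodic bin; ±180 are the same physical angle and wrap to +180.
- Empty orientation sets refuse to build a landscape; empty selections
  refuse to export (with the 200-particle guidance in the message) but are
  valid, logged selection results.
- Duplicate particle identifiers within one STAR file are interpreted as
  symmetry-expansion copies and numbered in file order (0, 1); pairing
  joins on (identifier, copy index) and rejects residual duplicates.
- Orthonormality tolerance 1e−9 (Frobenius), duplicate-orientation collapse
  1e−9, gimbal detection 1e−7°; STAR floats are written at 6 decimals, so
  file round trips are exact to 1e−6 by construction.

## Known limitations

- Only C2 point-group handling; higher symmetry groups would need the full
  operator set in the equivalence-class and canonicalization code.
- The per-axis Euclidean selection metric distorts for large β (where the
  z–y–x chart compresses); the geodesic option avoids this at the cost of
  no longer matching the plotted coordinate space.
- Hotspot detection is intentionally simple (threshold + strict maxima);
  it reports tail maxima in sparse diffuse regions rather than modelling
  the background.
- The tether model treats reach as a scalar budget: no linker ensemble,
  sterics, or β/γ dependence unless the optional grid mode is used.
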
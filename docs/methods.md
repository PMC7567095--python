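# Methods

`ratfield` computes the electric field that a TMS coil induces in a
small-animal head, and quantifies how much model detail that computation
needs.  This note documents the models, their assumptions, the numerical
choices, and what the synthetic phantom does and does not emulate.

## Physical model

Quasi-static conditions are assumed throughout: at TMS frequencies
(~kHz) displacement currents and propagation are negligible, so
`E = -dA/dt - grad(phi)` with the scalar potential determined by the
conductivity geometry.  The head is a piecewise-homogeneous, isotropic
volume conductor: a body compartment (sigma = 0.33 S/m) containing a bone
shell (6.6 mS/m, a 1/50 ratio).  Because the intracranial and body
conductivities are taken equal — the standard assumption — the skull can be
described by a *single closed surface bounding the bone volume*, holes
included, floating inside the body surface.  This is what makes skulls
with large openings (foramen magnum, orbital openings) tractable for a
boundary-element method, which otherwise requires closed surfaces with
constant conductivity jumps.

### Reciprocity

Rather than solving a vector problem per coil position, the E-field is
obtained through reciprocity with the magnetic forward problem: the
component of the induced field along a unit direction at a cortical point
equals `-dI/dt` times the magnetic flux the coil would pick up from a unit
current dipole at that point,

    E_i(r) = -dI/dt * sum_k w_k n_k . B(e_i at r; r_k),

summed over the coil's magnetic-dipole quadrature (weights `w_k`, loop
normals `n_k`).  `B` is supplied either by the closed-form solution for a
spherically symmetric conductor (Sarvas formula — independent of the
radial conductivity profile; radial dipoles are silent, so the induced
field is purely tangential) or by the BEM chain below.

### Linear-collocation BEM

Surface potentials satisfy a second-kind integral equation with the
double-layer (solid-angle) kernel.  Discretisation: linear (hat) basis on
surface vertices, collocation at vertices, with analytically integrated
element kernels.  For a planar triangle seen from collocation point `x`
the hat-function weights are

    W_i = a_i * Omega + d * (b_i . I1),   I1 = Omega n - sum_k f_k m_k,

with `Omega` the signed solid angle (van Oosterom–Strackee), `d` the
distance from `x` to the triangle plane, `b_i`/`a_i` the in-plane gradient
and offset of the hat function, `f_k` analytic edge integrals of `1/r` and
`m_k` in-plane outward edge normals.  A collocation point lying in a
triangle's plane (in particular at its own corners) contributes exactly
zero, so no special self-element handling is needed; the own-surface
diagonal is instead fixed by the interior solid-angle closure condition
(row sum `4*pi` from inside), which makes a constant potential an exact
discrete null vector for the insulated outermost surface.  That null space
is removed by rank-one deflation (`A + alpha 11^T/N`); the remaining gauge
constant provably cancels in all outputs, and the Geselowitz integrals
additionally project out per-surface constants so gauge invariance holds
to round-off rather than to quadrature accuracy.

The magnetic field of a solved source follows the Geselowitz formula
(infinite-medium term plus conductivity-jump surface integrals) with the
linear basis integrated exactly and the kernel sampled on a uniform
`4^depth` triangle subdivision (depth 1 by default, configurable; the
residual silent-source error is potential-limited, not quadrature-limited,
beyond depth 2).

Per coil placement the flux functional `a` (the linear map from surface
potentials to coil flux) is assembled once and a single adjoint solve
`x = A^-T a` yields the flux for *every* evaluation dipole as `x . s`,
where `s` is the cheap infinite-medium source vector.  This is
algebraically identical to solving three unit-dipole problems per
evaluation point (verified in the tests to 1e-8) and turns a
placement-grid run from thousands of solves into one factorisation plus
one triangular solve per placement.

Accuracy anchors (all enforced in tests): surface potentials of a dipole
in a homogeneous sphere match the analytic Legendre series to <1% RMS at
icosphere subdivision 4; the tangential-dipole magnetic field matches the
Sarvas formula to <1%; the full reciprocity E-field matches the
closed-form spherical solution to RE <2%; inserting a concentric resistive
shell changes the field by <3% (exact invariance holds analytically).
Known limitation: the silent-source residual of a *radial* dipole is
~1e-2 of the tangential scale at subdivision 4 and shrinks roughly
four-fold per subdivision — a plain linear-collocation floor; a
linear-Galerkin solver would do better and is out of scope.

## Coil model

The default coil is a small figure-of-eight (butterfly) coil: two wings,
three layers of four turns each, inner/outer winding diameters 24/47 mm,
9-mm wire stack whose lowest wire sits 2 mm above the casing bottom;
dipole layers at 1.5/4.5/7.5 mm above the lowest wire surface; default
stimulator setting dI/dt = 50 A/us.  Each turn is idealised as a planar
circular loop; turn radii are spaced evenly between the inner and outer
winding radius (winding pitch ignored).

A current loop is magnetically equivalent to a uniform dipole sheet over
any spanning surface, so each turn is represented by quadrature points
over its enclosed disk: area-weighted radial rings (6 per turn) with
azimuthal counts proportional to ring radius (32 on the outer ring, forced
even to keep the cloud 180-degree symmetric), ~2400 dipoles in total.
Concentrating a turn's whole area on the wire circle instead — tempting
because it looks like the winding — misestimates the field at head
distances by 50–135% against an exact Biot–Savart line-integral oracle;
the disk quadrature stays within ~1%.  The "thin coil" simplification
used in the resolution study keeps the full ampere-turns but places all
turns at the mid-stack height (4.5 mm).

Placement: the coil face is set tangentially on the scalp with a
configurable standoff; orientation angle 0 (the posterior–anterior
reference) is defined such that positive dI/dt induces a PA-directed
primary field under the coil centre.  Angles theta and theta+180 produce
the same dipole cloud with reversed sign (pure field reversal), so
placement grids cover [0, 180) by default.

## Synthetic phantom

The phantom emulates the structure of a small-animal CT study without any
real data: a prolate body outline (semi-axes 30 x 16 x 14 mm, the front
half of an adult rat); a 0.7-mm bone shell as an anterior-dorsal ellipsoid
(centre (6, 0, 2.5) mm, outer semi-axes 18 x 12 x 10 mm) whose crown lies
1.5 mm under the scalp; one posterior hole (12 degrees angular radius,
the foramen-magnum analogue) and two anterolateral orbital holes (10
degrees); an evaluation ("cortex") surface offset at least 1 mm inside
the inner skull sheet; optionally a posterior canal tube (spine variant).
Placing the skull anterior-dorsally rather than concentric with the body
is essential: the hole-funnelling effect that motivates skull modelling
requires a conductive volume *behind* the foramen for current to escape
into, as the neck provides in a real animal.

The bone shell is generated as an implicit solid — points within half a
thickness of the mid-sheet ellipsoid (first-order signed distance, so the
thickness is uniform along true normals), with each hole cut out such
that its rim is the half-torus around the hole-edge circle.  The rim
therefore keeps full bone thickness up to the edge, joins the sheets
tangentially and is convex everywhere, which makes the segmentation
recipe's 1-mm morphological closure a geometric no-op on it.  The surface
is extracted by marching cubes on a 0.2-mm grid and remeshed; with three
holes its Euler characteristic is -2 (genus 2), with none it is two
disjoint sheets (chi = 4).

Synthetic CT assigns Hounsfield units by surface containment (air -1000,
soft tissue +40, bone +1500; three clean histogram modes) on an isotropic
grid (0.17 mm by default, matching high-resolution small-animal
acquisitions) and adds seeded Gaussian noise.  What it does *not* emulate:
beam hardening, partial-volume blur, anatomical texture, soft-tissue
contrast gradations, or inter-animal variability — so a passing
segmentation round-trip shows the recipe's geometric fidelity under ideal
contrast, not robustness to scanner artefacts.

## Segmentation recipe

Thresholds from the HU histogram: air/soft halfway between the two
dominant modes (about -480 for the synthetic HU values); soft/bone at the
first 1-HU bin after the soft-tissue mode falls below 1% of its peak (the
"end of the soft-tissue peak", operationalised; the fraction is a
parameter).  Body = largest 26-connected component above the air/soft
threshold; bone = above the soft/bone threshold inside the body.
Morphological closure with spherical kernels (2 mm body, 1 mm skull;
kernel radius in voxels rounded half-up, implemented by exact Euclidean
distance transforms so large kernels stay fast and closing is exactly
idempotent).  Surfaces by marching cubes on a slightly smoothed level set
(sigma 0.6 voxels; if image noise leaves the level set too rough for
isotropic remeshing, extraction retries with progressively stronger
smoothing before failing), then isotropic remeshing; the cortex surface is the
boundary of (brain mask minus the skull mask dilated by the margin), the
brain mask being a user input (the phantom supplies its ground truth; no
automatic brain segmentation is attempted).

## Remeshing

Isotropic explicit remeshing in the split/collapse/flip/tangential-smooth
style, with back-projection of vertices onto the input surface after each
smoothing step.  Very dense inputs (marching cubes) are first bulk-
coarsened by batched, 1-ring-locked greedy edge-collapse rounds in a
compiled kernel.  Two safeguards matter for fidelity:

* a curvature-adaptive sizing field caps the local edge length at the
  local curvature radius where the surface turns sharply (more than
  ~34 degrees per edge, above the staircase noise of smoothed
  marching-cubes level sets), floored at 0.45x the global target — without it,
  collapses progressively shave sub-target-scale features such as the
  0.35-mm hole-rim torus (observed: up to 0.75 mm Hausdorff loss at the
  rims; with it the whole skull stays within one CT voxel of truth);
* coarsening of a closed mesh is refused outright (topology-change error)
  when a ray-cast interior-thickness probe shows the target edge would
  undersample a thin structure (threshold: thickness < target/3 — a
  Nyquist-like margin chosen so that a 0.7-mm shell may still be meshed at
  the 0.67–0.95 mm edges typical for such models).

Euler characteristic, closedness and orientation are preserved by
construction (link condition, fold checks) and re-verified on exit; the
mean edge must land within 20% of the target.

## Problem sizes and defaults

Defaults follow the study conditions the pipeline targets: skull meshed at
0.67 mm mean edge, body at 1.4 mm, CT at 0.17 mm voxels, dI/dt = 50 A/us,
placement grids of 15 x 10 mm at 2.5 mm spacing (7 x 5 = 35 positions)
with a 10-degree orientation step and theta ~ theta+180 equivalence (630
placements).  Tests and the acceptance script scale geometry down to
single-CPU sizes (icosphere subdivisions 3–4, phantom edges 0.9–3 mm, CT
at 0.25–0.4 mm) — chosen so each check still probes the same behaviour;
the mesh-halving convergence figure, for instance, is computed at
reference density 0.9/1.8 mm because the correlation error it measures is
already deep in the converged regime there.

## Known limitations

* Linear collocation only; the silent-source residual (~1% at working
  densities) bounds how well magnetically-silent configurations are
  reproduced.  A linear-Galerkin reference solver is deliberately not
  implemented.
* No eye compartments, no anisotropy, no CSF, no junctioned geometry; the
  skull-with-holes trick requires equal conductivity on both sides of the
  holes.
* The phantom is a geometric stand-in: quantitative figures transfer to
  real animals only to the extent the geometry does (e.g. the
  infinite-medium overestimation factor is ~2.3 on this phantom, smaller
  than reported for real rats whose brains are smaller relative to the
  coil).
* Sphere fitting assumes the crown region cleanly separates inner and
  outer skull sheets by radius; pathological geometries would need an
  explicit inner-sheet labelling.
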
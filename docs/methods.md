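# Methods

This note records the models, numerical choices and design decisions
behind `autoffr`, and what the synthetic phantoms do and do not establish
about behaviour on clinical scans.

## Image model and filtering chain

The CT volume is held as an 8-bit-normalised grey volume (0–255) with
anisotropic spacing (defaults 0.458 mm in-plane, 0.625 mm between slices).
All segmentation thresholds are expressed in this 8-bit vocabulary;
DICOM input is window/level-normalised on load (window configurable).
Whether a clinical deployment should filter raw Hounsfield units instead
is an open question flagged to users — every threshold here presumes the
0–255 normalisation.

Per slice, the chain is: wavelet-based noise estimate σ → non-local-means
denoising with filter strength 2σ (template 5 px, search window 7 px) →
Frangi vesselness (α = β = 0.5, γ = 15, Hessian scales 1–6 px, covering
coronary diameters at the stated pixel spacing) → grey threshold →
8-connected component-area filter (components strictly larger than
900 px removed).

Two choices deserve emphasis:

- **Classic NLM.** The uniform-patch-weight "fast" NLM variant measurably
  erodes bright tubes a few pixels wide at strength 2σ (a third of lumen
  voxels lost at threshold 125 under σ = 10); the classic
  Gaussian-weighted form preserves them (≈ 98% survival) and is used.
- **Vesselness as a gate.** The grey thresholds (125–145) act on the
  *denoised grey image*; the Frangi response is a multiplicative gate
  (`frangi_floor`, default 10⁻³) keeping only tubular-looking pixels.
  This keeps thresholding monotone — a higher threshold always yields a
  subset mask — while the gate suppresses flat bright regions such as the
  aorta interior.  Note β = 0.5 does not annihilate blob-like
  cross-sections (response ≈ e⁻² of the ridge response), which is
  necessary: a vessel running perpendicular to the slice appears as a
  small blob in-plane.

## Aorta landmark and cluster identification

The ascending aorta is found by a circular Hough transform (radii
25–60 px, Canny edges with 50/150 hysteresis) on slices 5–9 of the
cropped stack (1-based; the crop is a fixed fractional bounding box,
default central 60% in-plane).  The highest-accumulator circle per slice
is accepted and centres are averaged.  The radius window is what makes
the detection specific — nothing else of that size and circularity
appears near the heart on those slices.

Candidate voxels are clustered with DBSCAN at ε = 1.6 voxels and
MinPts = 2 in voxel-index space (a literal reading of the voxel-unit
setting despite anisotropic spacing; a mm-space metric is available via
config).  The two clusters whose points come nearest the reference (with
the reference placed at its mean detection slice) are the coronary trees;
left/right follows radiological display convention (patient-left coronary
on the image-right of the aorta).  Clusters below a minimum size (default
50 voxels) are not candidates: tiny residues of the area-filtered aortic
rim can sit arbitrarily close to the reference and would otherwise
outrank a tree.  Segmentation runs once per grey threshold (default five
copies at 125–145) and the per-threshold coronary voxels are merged by
union, which is what recovers distal segments whose contrast intensity
has decayed below the upper thresholds.

## Centreline, radii, 1D mesh

Cleaning applies the two DBSCAN passes as specified — voxels belonging to
any (ε = 7, 700 pts) cluster are removed as aortic root (only bulky dense
regions reach 700 points in a 7-voxel ball; a tube a few voxels wide
cannot), then voxels not in any (ε = 1.5, 3 pts) cluster are dropped —
followed by a morphological closing/opening with the 6-connected element.
Without that regularisation, single-voxel boundary roughness seeds
skeleton spurs and cycles.

The volume is thinned to a medial axis (Lee 3D thinning), split into
junction-free branches via the 26-connected voxel graph (junction voxels
have ≥ 3 neighbours; mutually adjacent junction voxels merge into one
junction node; cycles, which arise from residual surface roughness, are
broken at the longest edge of a spanning tree with a warning).  Leaf
branches shorter than 3 mm are pruned and degree-2 junctions re-fused.

Radii come from the marching-cubes lumen surface.  For each centreline
point, candidate wall vertices are restricted to a slab normal to the
local branch tangent (half-thickness 0.75 mm) — the "shortest *normal*
distance" reading — and the radius is the **median of the near ring**
(vertices within 1.8× the shortest slab distance), followed by a 5-point
running median along the branch.  The literal minimum distance is
available (`method="min"`) but is hypersensitive to single-voxel dents of
the binarised boundary: one missing boundary voxel drags the minimum a
full voxel inward, while the ring median — justified by the circular
cross-section assumption — recovers the radius to roughly a quarter
voxel.  Both estimators underestimate near bifurcations, where part of
the ring belongs to the sibling branch; this is accepted and the ostial
bias is handled by trimming.

Branches are resampled to equidistant nodes (default 0.01 cm) with PCHIP,
whose monotone shape preservation guarantees interpolated radii never
overshoot the sampled range.  The tree is rooted at the free branch end
nearest the aortic reference and oriented away from it; the first 5 nodes
of the root vessel are discarded (middle of the 4–6 range), because
aortic-root cleaning bites unreliably into the ostium.  The
minimum-radius query point is reported as the node nearest the centroid
of the near-minimum plateau (radii within 0.005 cm of the minimum) —
quantised radii make the raw argmin land at an arbitrary plateau edge.

## Haemodynamic model

1D mass and momentum balance on each vessel in (A, Q) variables, with the
viscous friction −22πμQ/A² (a polynomial axial velocity profile) and the
advective term ρ/A ∂ₓ(Q²/A), closed by the elastic tube law with
radius-dependent reference wave speed c₀(r₀) (constants k₁ = 2×10⁷
g/(cm·s²), k₂ = −22.53 cm⁻¹, k₃ = 8.65×10⁵ g/(cm·s²); the units follow
from requiring c₀ in cm/s).  The exponent b defaults to 2 (the square-root
tube law) unless a collapse pressure is configured, in which case
b = 2ρc₀²/(P₀ − P_collapse) per node.  A visco-elastic term
Γ/A₀^{3/2}·∂A/∂t is supported with Γ = 0 by default — the elastic part
fully determines the steady pressures that cFFR is built from.  P₀
defaults to MAP (93.33 mmHg): CCTA is acquired near mean pressure, so the
imaged lumen area is taken as the area at mean pressure.

Boundary conditions: prescribed periodic inflow per coronary side and a
three-element bed per terminal.  R₁ = ρc₀/A₀ at the terminal node is the
characteristic impedance; the remaining bed resistance RTf − R₁ splits
0.79/0.21 between the arterial and venous micro-circulation (grouped so
that R₁+R₂+R₃ = RTf — the only grouping under which the printed split
sums correctly).  RTf per terminal is Rcor/fᵢ with Murray fractions
fᵢ ∝ rᵢ^2.27 on terminal end radii, and Rcor = MAP/Q̄ per side.  Bed
compliances (total 6×10⁻⁵ cm⁵/dyn per side, 20% arterial / 80%
intramyocardial) are distributed in proportion to fᵢ; the intramyocardial
capacitor references a scaled ventricular pressure (idealised sin²
systolic pulse, scale 0.5 left / 0.2 right), which produces the systolic
throttling of coronary inflow.  These compliance and scaling values are
representative, not patient-calibrated, and are config-exposed.

Default inflow waveforms are analytic raised-cosine compositions —
diastolic-dominant on the left (mean 2.0 cm³/s), more uniform on the
right (mean 1.0 cm³/s), period 0.8 s — editable or replaceable by CSV
tables.  They stand in for waveforms that would clinically come from a
closed-loop systemic model; with fixed per-side mean flows, cFFR here
reflects geometry, not patient physiology.

### Discretisation

Nodal collocation finite differences: BDF2 in time (backward Euler on the
first step), second-order central differences in vessel interiors and
second-order one-sided differences at vessel ends.  Unknowns are (A, Q)
per node plus two compliance-node pressures per bed.  At junctions, mass
conservation and continuity of static pressure are imposed (a
total-pressure variant is config-selectable); at terminals the 1D
pressure couples through R₁ to the first capacitor node.  Each time step
solves the full nonlinear system by damped Newton iteration on an
analytic sparse Jacobian (LU factorised each iteration).

Numerical settings: Δt = 10⁻⁴ s default, Newton tolerance 10⁻¹⁰ on
row-scaled residuals (momentum/pressure rows scaled by MAP, flow rows by
the peak inflow), at most 25 iterations with step halving; a stalled
iteration is accepted below 10⁻⁶ — in the near-rigid limit the residual
floor is set by rounding of the tube law, not by the iteration.  On
non-convergence the step is redone as two half steps (up to 4 levels).
Simulations run up to 5 cycles with early exit when consecutive cycles'
inlet pressure differs by < 0.5% in L2.  A steady mode drops all time
derivatives and closes the beds algebraically; it serves both as the
initialiser of pulsatile runs (which makes periodicity converge in a few
cycles) and as a fast solver for steady questions, with a flow-ramp
continuation fallback for severe stenoses.

cFFR is the cycle-mean pressure ratio distal/inlet (reducing to the plain
ratio for steady solutions).  Whether a specific cycle phase would be
preferable is unresolved; the mean-ratio convention is implemented and
stated.  Mass conservation at junctions holds to Newton precision
(~10⁻¹⁶ relative in practice); the observed temporal order on a
near-rigid tube is ≈ 2.0.

## Synthetic phantoms

The generator emulates the scan characteristics the pipeline expects:
0.458/0.625 mm spacing, coronary intensities fading 150 → 132 proximal to
distal (so the 125–145 multi-threshold union is genuinely exercised),
background 60, additive Gaussian noise clipped to [0, 255], default
volume 256×256×48.  The standard coronary phantom has an aorta cylinder
(radius 40 px, superior slices), two coronary trees each with one
bifurcation sprouting with clearance next to the aorta, a 50% cosine
stenosis on the left main, and a distant decoy vessel standing in for a
pulmonary branch; tube axes are PCHIP-interpolated polylines rasterised
by distance (voxel centres within r(x) of the axis).  Everything is
byte-reproducible from (spec, seed), and ground-truth masks, axes and
radius profiles are always returned.

What the phantoms do **not** emulate: partial-volume intensity gradients
at the lumen boundary, beam hardening, motion artefacts, calcification,
stents, anatomically realistic background tissue, or the near-contact
geometry of the true aortic root–ostium junction.  Passing phantom tests
therefore demonstrates correctness of the algorithmic chain under the
stated image model, not clinical segmentation accuracy.  The σ = 10
geometry-recovery runs sit at the resolution limit: the maximum
radius-profile error across noise seeds is 0.17–0.32 mm, i.e. about half
of the largest voxel dimension, with the residual spread set by which
boundary voxels the noise pushes across the threshold.

## Known limitations

- Circular cross-sections throughout; no elliptic lumen or plaque model.
- Radius underestimation at bifurcations (shared-wall effect).
- Leaks near the aortic root in low-quality scans are not repaired; the
  cleaning stage simply removes dense root voxels and the ostial nodes
  are trimmed.
- Coronary dominance is not modelled; boundary conditions are identical
  across subjects by construction.
- The hyperaemic state is implicit in the prescribed inflows/resistances;
  there is no pharmacological model.
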
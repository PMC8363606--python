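# Methods

`stentsim` is a desk-scale, fully synthetic re-implementation of an
image-based coronary bifurcation stenting workflow: 3D reconstruction
from biplane angiography plus OCT, OCT-based plaque scoring with
hyperelastic material assignment, multi-step device deployment, stent
reconstruction from OCT strut points, reduced-order hemodynamics, and
Bland–Altman validation of diameter profiles. Every stage is exact or
analytically checkable on the synthetic inputs, which is the point: the
package trades continuum fidelity for a pipeline in which every
contract can be tested on one CPU in seconds.

## Coordinates and conventions

Right-handed coordinates in mm. Centerline arclength is measured from
the proximal main-vessel (MV) inlet; the side branch (SB) continues the
arclength through the carina (its first slice sits at the carina
arclength). The carina is the fixed landmark for all co-registration.
Circumferential angles are counter-clockwise from the SB-ostium
direction; frames along a centerline are rotation-minimizing (double
reflection), so no spurious twist enters any round trip.

## Synthetic anatomy (the study conditions)

The generator's defaults define the reference case used throughout the
tests and the acceptance script: proximal MV 3.5 mm tapering to 3.0 mm
over 40 mm, SB 2.5 mm at 60°, wall thickness 0.9 mm, and a 60%
diameter stenosis of 8 mm length centered at 32 mm (distal MV). These
are ordinary values for a left-anterior-descending-type bifurcation; a
scientist would call a 60% diameter stenosis an intervention-worthy
lesion. Stenoses are cosine-tapered, so the minimum diameter is an
analytic product (taper × (1 − stenosis fraction)) and every profile
oracle is closed-form. Stenoses within one vessel diameter of the
carina are rejected: the carina must stay clean because it anchors
co-registration.

OCT pullbacks are sampled at 0.5 mm spacing (0.2 mm where stent struts
are detected), 64 points per contour, ordered distal→proximal.
Composition arcs partition the circumference proportionally to the
local lipid/fibrous/calcified fractions at a seeded random start angle.
Dropout (missing outer-border arcs) is injected by an explicit sampler;
no global random state exists anywhere — all randomness flows through
`numpy.random.Generator(seed)`.

What the generator does **not** emulate: pixel-level image appearance,
cardiac-phase motion, cone-beam projection geometry, eccentric or
non-circular lumina (contours are circular; eccentricity enters only
through plaque scoring), and guidewire artifacts. Tests passing on
these inputs therefore demonstrate the pipeline's internal consistency
and its contracts, not segmentation robustness on clinical images.

## Biplane reconstruction

Projection is parallel (orthographic), not cone-beam: a view at angle φ
looks along (cos φ, sin φ, 0) with image axes u = (−sin φ, cos φ, 0)
and v = ẑ. Views closer than 30° are rejected. Both images share the
v ≡ z axis, so when both curves are monotone in v the correspondence
problem is solved exactly by pairing samples at equal v (the parallel
analogue of epipolar matching); otherwise pairing falls back to common
arclength fraction. Each 3D point is the least-squares solution of its
four projection equations. On noiseless synthetic projections the round
trip is exact to machine precision, comfortably inside the 0.05 mm mean
acceptance bound. This sidesteps the foreshortening/out-of-plane error
handling of clinical reconstruction software and must not be presented
as equivalent to it.

## OCT completion, alignment, lofting, merging

Missing outer-border arcs follow a pure threshold rule on the total
missing span: < 180° → fill by periodic cubic spline through the
visible border; > 180° → discard the frame. Exactly 180° is treated as
interpolable (the inclusive-lower-branch choice; the source rule states
strict inequalities both ways, leaving the boundary open). DISCARD is a
value, not an error; lofting skips discarded frames and spans the gap.

Frame i lands at arclength `carina + direction·(i − carina_index)·spacing`
and is oriented by the rotation-minimizing frame, with absolute
rotation fixed by the SB-ostium direction at the carina frame (the
rotational registration of OCT is otherwise unobservable; this is the
documented convention). Branch merging is an implicit boolean union:
each branch is an analytic tube field (radius at nearest centerline
sample minus distance), the union is the max of the fields, and
marching cubes at level zero (default grid pitch 0.15–0.2 mm) remeshes
it — watertight by construction, no ray-casting or CAD kernel
required. The SB ostium area is reported analytically as the oblique
cylinder ellipse π r_sb² / sin(angle).

## Materials

All soft tissues are isotropic incompressible (J = 1 exactly) reduced
polynomial solids, W = Σᵢ C_i0 (I₁ − 3)ⁱ up to sixth order, with
uniaxial Cauchy stress σ(λ) = 2(λ² − 1/λ) Σᵢ i C_i0 (I₁ − 3)^(i−1).
The coefficient table (bench silicone C10 = 0.154 MPa; normal wall
six-order set; five plaque classes very_soft…very_stiff with yield
stresses 0.12, 0.71, 1.37, 1.81, 627 MPa) ships as a versioned JSON
resource. The listed plaque yield stresses are implemented as a
perfect-plasticity cap on the stress magnitude — the simplest closure
when only a yield value is given. A consequence worth noting: the
thin-wall pressure p = (t/r)·σ is then flat-to-decreasing once a
material caps (very_stiff caps near λ ≈ 1.21), so strict monotonicity
of wall pressure holds only below cap onset and the equilibrium solver
does not assume global monotonicity (scan + bisection).

Class ordering is asserted at λ = 1.2, not in the small-strain limit,
because C10(soft) = 0.01 < C10(very_soft) = 0.045 — the table's classes
order by large-strain behavior only.

The plaque score maps per-zone composition to a quarter-step value in
[−2, +2]: raw = 2(f_ca − f_lipid)/(f_ca + f_fib + f_lipid), rounded to
the nearest quarter with ties toward zero. The exact weighting used
clinically (area vs circumference vs thickness) is not public; this
area-fraction contrast is this package's documented stand-in, isolated
behind one function so it can be swapped. Fractional scores interpolate
stress pointwise-linearly between the two adjacent class curves.

Alloys are bilinear elastoplastic: MP35N (233 GPa, 414 MPa yield,
930 MPa tensile at 45% elongation) and Pt–Cr (203, 480, 834, 45%) with
linear isotropic hardening; the Pt–Ir core (224 GPa, 285 MPa) is
perfectly plastic. The shell-core wire is an area-weighted effective
alloy (default 25% core). Balloons are linear elastic membranes at
300 / 900 / 1500 MPa for compliant / semi-compliant / non-compliant.

## Device models

Stents are parametric ring-and-link graphs: rings of 2×crowns nodes
(alternating valleys and peaks) joined by crown arms, adjacent rings by
links. Proprietary commercial patterns are not available; the presets
(`integrity_like`, `onyx_like`, `synergy_like`) carry only family,
strut section and alloy and are representative, not replicas. Crimping
is a pure radial scaling (exactly invertible); positioning/bending maps
node (z, θ, r) to C(s₀+z) + r·(cos θ e₁ + sin θ e₂) along the
rotation-minimizing frame — a rigid motion on a straight vessel.

Balloon compliance is closed-form: folded (d_nom/4) below a 2 atm
unfolding threshold, linear ramp to nominal diameter at nominal
pressure, then membrane growth d_nom(1 + ΔP·d_nom/(2 t_b E)) with
default membrane thickness t_b = 0.03 mm. At 3 mm / 900 MPa this gives
≈ 0.56%/atm above nominal — at the soft end of semi-compliant catalog
compliance. Pressures are carried in atm as tables print them and
converted at 0.101325 MPa/atm.

## Deployment surrogate

The central modeling decision: the 3D explicit finite-element contact
problem is replaced by a chain of independent cross-sectional
equilibria at 0.25 mm slice spacing (0.50 mm halves to it in the
convergence check, mirroring the <1% mesh criterion of the full-physics
workflow). At each slice the balloon pressure balances

    P = p_wall(r) + p_plaque(r) + Σ p_ring(r),   r ≤ r_balloon(P).

* **Wall**: thin-walled hoop relation p = (t/r)·σ(λ), λ = r/r_healthy,
  engaged only in tension. `r_healthy` is the disease-free taper
  radius.
* **Plaque**: diseased slices (lumen below the healthy taper) add a
  second layer of thickness (r_healthy − r0) loaded at λ = r/r0 with
  the score's stress curve. This term acts **only while loading past
  the largest radius the slice has ever reached**: plaque deformation
  is permanent (dissection/compaction), so recoil does not claw back
  balloon-acquired lumen. Without this one-way behavior the capped
  plaque stress (≈ 0.9 MPa inward for a stiff lesion) would crush any
  realistic stent on deflation.
* **Rings**: each stent layer is a 1D elastoplastic hoop spring,
  elastic slope ∝ k·E·A/r³ with return-mapping plasticity on the alloy
  law; the plastic set radius is what survives deflation. The
  dimensionless ring constant k = 0.1 encodes that a zig-zag ring
  expands by crown bending, roughly an order of magnitude softer than
  stretching the wire in hoop; with the preset strut sections this
  places radial collapse strength near 1 MPa, enough to hold soft and
  neutral lesions and to under-expand against stiff ones — which is
  exactly the clinical signature the score is meant to reproduce.

Equilibria are found by a 128-point scan plus bisection to 1e-6 mm
(robust to the non-monotone capped regions). Inflation never shrinks a
slice; recoil never grows one; unstented slices return to their
reference radius exactly. Procedure steps (stent, POT, SB strut
opening, KBI, pre/post-dilatation) replay tables whose rows carry
device, size, pressure in atm, and placement (absolute, or "more
proximally than step #k" by an offset). POT windows are clipped at the
carina. SB strut opening clears the jailed markers and attaches the
opened stent cell as a scaffold layer to the ostium slices (the
recrossing cell is always the distal cell); the ostium-area bookkeeping
is a stated simplification. KBI models the proximal-MV overlap as the
area sum of the two balloons (area-equivalent radius √(r₁²+r₂²))
driven at the larger of the two pressures. TAP/culotte SB stents
protrude into the proximal MV (2–5 mm by template), producing the
two-layer overlap; overlapping layers simply sum their ring pressures —
no strut-strut interlocking. Frictional contact (0.2), 0.05 s inflation
and 5×10⁻⁸ s increments of the full-physics solver are logged as
provenance metadata, tagged recorded-not-simulated.

State snapshots serialize to sorted-key JSON with repr-exact floats, so
step chaining is bitwise reproducible and is tested that way.

## Stent reconstruction from OCT

Detections (per-frame angle/radius points, here simulated by snapping
deployed-stent nodes to 0.2 mm frame planes) are unrolled to a (z,
θ·r̄) chart, registered to the unrolled design pattern by grid search
over periodic rotation and axial shift, and assigned one-to-one by
minimum-cost bipartite matching with a 0.3 mm distance gate; residuals
above half the gate set a low-confidence flag rather than failing
silently. Ring-and-link patterns are rotationally symmetric under one
node spacing, so the recovered rotation is meaningful only modulo that
symmetry — the equivariance test accounts for it. Unmatched nodes are
filled from the registered pattern so the output graph always carries
the design's full topology; matched nodes land on the lumen surface
inset by half the strut thickness. Strut volume is swept as per-edge
capped tubes. The full round trip (deploy → detect → reconstruct) has
node RMSE dominated by the 0.2 mm axial frame quantization
(≈ 0.06 mm), below one strut width.

## Hemodynamics

A 1D Poiseuille surrogate for transient 3D CFD. Carreau viscosity
μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^((n−1)/2) with μ∞ = 0.0035 Pa·s,
μ0 = 0.25 Pa·s, λ = 25 s, n = 0.25; blood density 1060 kg/m³. The
Poiseuille wall shear rate γ̇_w = 4Q/(πr³) is flow-driven and
independent of viscosity, so the nominal fixed point τ = μ(γ̇_w)·γ̇_w
closes in a single step (verified to 1e-8); the Newtonian limit is
exact. The branch flow split is the Huo–Kassab law Q_mv/Q_sb =
(d_mv/d_sb)^(7/3). The inlet scaling rule of the source workflow is not
printed; the mean inlet flow here scales as (D/3 mm)^(7/3) — reusing
the HK exponent keeps inlet and outlet scaling self-consistent, and the
exponent is configurable. The packaged waveform is a generic smooth,
strictly positive, two-harmonic pulse with mean 1.0 mL/s at the 3.0 mm
reference and 0.8 s period — a stand-in, config-replaceable. The
3-cycle washout and 10-diameter inlet/outlet extensions of the 3D
solver are no-ops in 1D and are retained as metadata only. TAWSS is the
cycle mean of τ per slice.

## Comparison harness

MLD is the per-slice area-equivalent diameter 2√(A/π) (the per-slice
definition is not published; a mean-chord alternative is accepted via
explicit diameters). MSD is the diameter of the stent-ring radius
profile over stented slices; empty slices are absent, not zero.
Profiles co-register by shifting carina to zero and interpolating the
reference at simulated samples. Bland–Altman uses the sample (n−1)
standard deviation and fixed 1.96 multiplier, so bias ≡ midpoint of the
limits by construction — the identity that the printed agreement tables
satisfy and that the acceptance script exploits. "Overall" rows pool
all paired differences (a fresh analysis on the pooled set), never
average per-case biases.

Reproducing the published agreement values themselves would require the
non-public bench μCT and clinical OCT images; the package makes no such
claim and validates the machinery instead.

## Numerical choices and degenerate inputs

Bisection tolerances: 1e-6 mm (deployment), 1e-8 relative (WSS).
Quarter-score rounding ties go toward zero. Marching-cubes pitch
0.15–0.2 mm. Zero-length strut edges are skipped with a warning;
all-degenerate inputs raise. Frames beyond the centerline truncate with
a warning. Procedure files with forward step references are rejected;
balloon steps before any stent warn but proceed. Problem sizes
throughout (40 mm vessel at 0.25 mm slices, 81–161 frames, 160-node
stents, 64-sample waveforms) were chosen so the full test suite and the
acceptance script each run in well under a minute of CPU — the analytic
oracles, not scale, carry the validation.

## Known limitations

No 3D contact mechanics, no wall stress/strain fields, no drug elution
or thrombosis, no anisotropy/viscoelasticity/pre-stress of the wall, no
cone-beam geometry, no image-intensity strut detection, no oscillatory
shear index. The slice-equilibrium surrogate preserves the procedure
grammar, the constitutive laws and the qualitative mechanical contracts
(monotonicity, recoil, plastic retention, stiffness effects), not
stress fields or strut-level apposition patterns.
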
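# stentsim

Desk-scale, fully testable simulation of patient-specific coronary
bifurcation stenting. The package is aimed at researchers in
image-based cardiovascular biomechanics who want the *pipeline* of a
clinical stenting-simulation platform — 3D reconstruction from biplane
angiography and OCT, plaque scoring and material assignment, multi-step
device deployment, stent reconstruction from OCT strut points,
hemodynamics, and agreement statistics — in a form where every stage
runs in seconds on a laptop and is verifiable against analytic ground
truth. Clinical and bench imaging of this kind is not publicly
available, so a first-class synthetic generator produces every input
the pipeline consumes.

## What it computes

* **Synthetic anatomy & OCT** — tapered bifurcations with
  cosine-shaped stenoses, per-frame lumen/outer contours with
  lipid/fibrous/calcified composition arcs and signal-dropout,
  parallel biplane projections, bench-silicone variants, and procedure
  tables in the provisional / TAP / culotte step grammar.
* **Reconstruction** — centerline fusion from two angiographic views;
  the outer-border rule (missing arc < 180° → interpolate, > 180° →
  discard the frame); carina-referenced pullback alignment; lofting;
  watertight branch merging.
* **Materials** — reduced polynomial hyperelasticity
  W = Σᵢ C_i0 (I₁−3)ⁱ for wall, plaque and bench silicone; a
  quarter-step plaque score in [−2, +2] (−2 lipid only … +2 calcium
  only) mapping OCT composition to one of five stress–strain classes
  with yield caps; bilinear elastoplastic stent alloys; balloon moduli
  300/900/1500 MPa by compliance class.
* **Deployment** — a quasi-static slice-equilibrium surrogate
  replaying clinical procedure tables (stenting, POT, SB strut
  opening, KBI, pre/post-dilatation) with elastoplastic stent rings,
  recoil, plastic set, jailing/unjailing and two-stent overlap; state
  chains bitwise-reproducibly across steps.
* **Stent-from-OCT** — unroll strut detections, register to the 2D
  design pattern, bipartite-match points to nodes, wrap back onto the
  lumen centerline, add strut volume.
* **Hemodynamics** — Carreau blood rheology
  (μ∞ = 0.0035 Pa·s, μ0 = 0.25 Pa·s, λ = 25 s, n = 0.25), pulsatile
  inlet scaled by diameter, Huo–Kassab flow split
  Q_mv/Q_sb = (d_mv/d_sb)^(7/3), per-slice Poiseuille WSS and TAWSS.
* **Comparison** — MLD/MSD diameter profiles, carina co-registration,
  Bland–Altman bias and 95% limits of agreement (bias ± 1.96·SD), and
  method-comparison tables with pooled overall rows.

The full scientific account — model assumptions, parameter defaults
and why, surrogate constants, and what the synthetic tests do and do
not demonstrate — is in [`docs/methods.md`](docs/methods.md).

## Worked example

Replaying a provisional stenting procedure (MV stent at 16 atm → POT →
SB strut opening → kissing balloons) on the reference synthetic case, a
3.5→3.0 mm main vessel with a 60% stenosis
(`python examples/04_deployment.py`):

```
pre-procedure in-lesion MLD: 1.24 mm
after step 1 (  stent @ 16 atm = 1.62 MPa): in-lesion MLD 1.64 mm
after step 2 (    pot @ 16 atm = 1.62 MPa): in-lesion MLD 1.64 mm
after step 3 (sb_open @ 14 atm = 1.42 MPa): in-lesion MLD 1.64 mm
after step 4 (    kbi @ 12 atm = 1.22 MPa): in-lesion MLD 1.64 mm
max strut-wall gap after the full procedure: 0.000 mm
SB ostium area: 6.29 mm^2
```

The minimum lumen diameter in the lesion grows from 1.24 mm to 1.64 mm
acutely: the balloon yields the stent rings plastically, the neutral
(fibrous) plaque deforms permanently, and the stent's plastic set holds
the gain through recoil. POT and KBI act proximal of the carina, so the
in-lesion MLD is untouched by them, while the SB ostium area increases
when the jailing struts are opened. Running the companion hemodynamics
example shows the peak time-averaged wall shear stress at the lesion
dropping from 16.4 Pa to 1.1 Pa once the lumen is restored.

Each capability has a runnable script under `examples/`; the CLI
(`stentsim synth|simulate|flow|compare`) wraps the same library calls
for shell use.

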
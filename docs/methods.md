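# Methods

`perfushear` packages two computational procedures used to study 3D ovarian
cancer micronodules grown under flow in a perfusion microchannel: (i) a
steady-flow model of the shear stress and penetration flux on an elliptical
nodule in the channel, and (ii) the image-quantification pipeline that turns
tiled calcein-AM confocal stacks into a normalized viable tumor area, plus
the statistics used to compare dose-response groups. A synthetic-data
generator emulates the microscope output with exact ground truth so every
pipeline stage is testable end to end.

## 1. Channel-flow model

### Governing equations

The perfusion channel has cross-section w × h = 4 mm × 254 µm and is driven
at Q = 2 µL/min. The Reynolds number at the mean velocity
U = Q/(w·h) ≈ 0.033 mm/s is ~1e-5, so inertia is negligible and the flow is
Stokes flow. The model is 2D in the XZ plane (unit depth): a rectangular
channel section of height h = 250 µm and length 2.2 mm, with an elliptical
nodule (semi-axes a × b, a = 40–100 µm along the flow, b = 40 µm vertical)
centred at (0, z0) with z0 = protrusion − b = 20 µm, so it protrudes 60 µm
above the floor. In the fluid,

    mu ∇²u − ∇p = 0,   ∇·u = 0,

and inside the nodule the Brinkman drag (mu/kappa)·u is added, modelling
seepage through a porous medium of permeability kappa. A solid
(impermeable) nodule is realised by the same penalization with
kappa = 1e-18 m², which drives the interior velocity to ~1e-10 of the mean
flow; the solid-limit consistency test (kappa → 0 porous solution matches
the solid one) validates this route.

Boundary conditions: no-slip floor and ceiling; fully developed parabolic
inlet with mean U; zero gauge pressure at the outlet. The nodule sits
≥ 1 mm from the inlet and outlet; entrance effects decay like exp(−πx/h),
so the near-nodule field is unaffected by the boundary treatment.

### Discretisation

Uniform staggered (MAC) grid — u on vertical faces, w on horizontal faces,
p at cell centres — which is inf-sup stable and conserves mass exactly per
cell. Default cell size 2.5 µm (b/16); the solver refuses cells coarser
than b/10. The wall ghost values use mirror reflection; the outlet uses a
one-sided pressure closure that is exact for developed flow. The sparse
system is solved with a direct LU factorisation, so results are
deterministic for a given mesh; the reported residual is the backward
error ‖Ax−b‖/(‖A‖‖x‖+‖b‖), typically ~1e-17 or better.

The analytic plane-Poiseuille anchors (u(z) = 6U(z/h)(1−z/h),
tau_w = 6·mu·Q/(w·h²) ≈ 7.75e-4 Pa = 0.00775 dyn/cm² for the chip) are the
validation oracle: the empty-channel numerical floor shear must agree with
the closed form within 5% (it agrees to ~1% at 4 µm cells).

### Shear and flux profiles

The exposed surface (the part of the ellipse above the floor) is sampled at
181 polar angles. Shear sigma = mu ∂u_t/∂n is estimated by a quadratic fit
through the interpolated tangential velocity at 1, 2 and 3 cells outside
the surface, extrapolated to the interface. The fit deliberately does not
assume u_t = 0 at the surface: a permeable nodule carries a genuine slip /
seepage velocity there, and wall-anchored estimators convert that slip into
spurious shear (with the sign of the bias depending on the formula). One
estimator for all cases keeps porous/solid comparisons meaningful. Profiles
are reported raw (Pa) and normalized by the analytic tau_w.

The penetration flux q = −u·n (positive into the nodule) is sampled two
cells inside the surface, where the field is the smooth Darcy seepage flow
and interpolation does not straddle the sharp interface. The nodule base
lies on the no-slip floor and carries no flux, so the closed-surface mass
balance reduces to the integral over the exposed arc, which the tests
require to vanish within 2% of max|q| times the arc length.

Because the peak of the shear profile sits on a flat plateau around the
apex, the "highest shear where the flux is zero" property is checked as:
the shear at the zero-flux point is within 5% of the profile peak
(comparing argmax locations on a plateau is ill-conditioned).

### Parameters and defaults

| parameter | default | why |
|---|---|---|
| mu | 1.0e-3 Pa·s | water-like culture medium; reproduces the 0.008 dyn/cm² anchor |
| rho | 1000 kg/m³ | carried for completeness; inertia-free model |
| h (simulated) | 250 µm | the simulated central section; the physical chip spacer is 254 µm and the analytic anchors use it |
| kappa | 1e-11 m² | see below |
| porosity | 0.3 | reporting only; does not enter the Brinkman momentum balance |
| cell size | 2.5 µm | resolves b/16 and the kappa=1e-11 seepage length |

The permeability of a loose tumor-cell aggregate is not well constrained;
values quoted for tissue span orders of magnitude. The default
kappa = 1e-11 m² was chosen on numerical grounds: the Brinkman seepage
length sqrt(kappa) ≈ 3 µm must be resolvable by the grid for the
porous-vs-solid shear contrast to be a property of the physics rather than
of the discretisation. At kappa ≤ 1e-13 the seepage layer (≤ 0.3 µm) is far
below any feasible cell size and the measured contrast is estimator
artifact. All porous conclusions drawn by the tests are ordering
statements (porous peak < solid peak, monotone in kappa), not values tied
to a particular kappa, and kappa is configurable.

### Limitations

2D XZ model with unit depth (no spanwise variation); rigid, non-growing
nodules; sharp-interface penalization (no Beavers–Joseph slip calibration);
Newtonian medium. Peak normalized shear values are mesh-converging but
reported at the default mesh; only trends across geometry/porosity are
treated as conclusions.

## 2. Synthetic calcein datasets

The generator emulates the acquisition used for perfusion channels: a
13 × 3 grid of 512 × 512 tiles with 10% overlap (stitched mosaic
6044 × 1434 px) and ~18 Z-planes at a 10 µm step. Nodules are filled
ellipses with log-normal areas (median 3000 µm², sigma 0.45, clipped to
800–12,000 µm²), non-overlapping by construction, one of them deliberately
centred on a tile seam so cross-tile merging is always exercised. Each
nodule spans 2–4 adjacent planes with a triangular intensity profile
peaking at 1, so the maximum intensity projection recovers the full signal.
Pixel size defaults to 2.5 µm (a 512 px tile spans 1.28 mm; a 2000 µm²
nodule is ~320 px); it is configurable, and all thresholds are specified in
µm².

Intensities: background 20, live signal 120, dead (formalin-killed) signal
30 arbitrary units; noise is Poisson shot noise on the signal plus additive
Gaussian read noise (sd 3), giving SNR ≈ 9 at the live level. Calibration
fields (uniform live and dead) emulate the untreated vs formalin wells used
to fix the calcein dynamic range.

Determinism: every tile/plane draws from a stream keyed by
(seed, row, col, plane), so renders are lazy, idempotent and independent of
traversal order, and identical specs produce bit-identical data.

Dose-response experiments plant a control scene per replicate and, for each
dose with survival fraction f, kill whole nodules (flip them to the dead
intensity) and gently shrink the survivors (area factor ≥ 0.7) so the
planted viable area equals f times the control area times a replicate-level
noise factor (CV 0.08 by default). The default fractions
(1, 0.93, 0.82, 0.83, 0.55, 0.18) at doses (0, 10, 25, 50, 250, 500) µM are
the printed static-culture group means; the generator records exact planted
areas in a truth table. What the generator does **not** model: optical PSF
(objects are hard-edged), spectral bleed-through, photobleaching, uneven
illumination, focus drift and tile mis-registration. Passing tests
therefore demonstrate the correctness of the pipeline's arithmetic and
merging logic on in-regime data, not robustness to those optical effects.

## 3. Quantification pipeline

Calibration places the global intensity floor midway between the robust
(median) levels of the dead and live reference images and fails loudly if
the two are not separable. Segmentation marks a pixel calcein-positive when
it exceeds its 101-px local-window mean by 0.35 × the calibrated dynamic
range *and* clears the floor; polarity is bright-objects-on-dark. The
sensitivity default keeps interiors of in-regime objects (≤ ~12,000 µm²,
i.e. well under the window area) from being hollowed out while an inverted
or uniformly bright image segments to nothing.

Stitching places tiles at a 461 px stride and fuses the 51 px overlap
strips by pixelwise maximum (robust to illumination mismatch, exact for
noiseless tiles). Per-plane masks are OR-ed into the composite binarized
mask; the MIP is kept for the mask × MIP product image used in displays —
areas are computed from the composite mask, which is the product's support,
so the two are equivalent for quantification. Components are labelled with
8-connectivity, converted to µm² via pixel_size², and objects below the
minimum nodule size cut-off (default 2000 µm², sweepable 500–3000 µm²) are
discarded. Static cultures use the same segmentation on a single focal
plane with no projection.

Streaming mode processes one tile-column band at a time. Each band is
stitched and segmented with a halo of half the adaptive window so the
local-mean context matches the whole-mosaic computation exactly, and object
fragments are merged across band seams with union-find under
8-connectivity. The result is identical to whole-mosaic processing (the
tests assert exact equality, including with noise) while at most two
adjacent tile columns are resident — well under the two-grid-rows memory
bound the streaming contract targets.

Normalization divides each sample's live area by the mean live area of its
own no-treatment control group (same growth condition and experimental
round), so control groups have mean 1 by construction.

## 4. Statistics

Summaries are mean ± SEM (sd with n−1, SEM = sd/√n; n = 1 reports 0 with a
warning). Two-group comparisons: Welch's t and Mann-Whitney U (exact null
for both n ≤ 8 without ties, normal approximation with tie correction
otherwise; two zero-variance equal groups give p = 1 by convention).

Many-to-one comparisons use one-way ANOVA followed by Dunnett-style
adjusted p-values computed from a seeded Monte-Carlo sample (default 1e5
draws) of the multivariate t distribution of the control contrasts
(correlation rho_ij = lambda_i·lambda_j, lambda_i = sqrt(n_i/(n_i+n_0)),
pooled-variance df). The reference sample depends only on the design, so it
is reused across same-design datasets; tests cross-check the adjusted
p-values against an independent implementation and verify the single-
contrast case collapses to the pooled two-sample t. The rank-based variant
is Kruskal–Wallis with Dunn's many-to-one z tests, Bonferroni-adjusted.

The size-cut-off sensitivity analysis treats the cut-off as a
within-replicate factor and runs a repeated-measures one-way ANOVA per
treatment group over the 500–3000 µm² sweep (identical areas at all
cut-offs short-circuit to p = 1); the channel is "threshold-stable" when
no group shows p ≤ 0.05. Fold changes are reported at full precision and
rounded to two significant figures; the percent tumoricidal effect is
100 × (1 − normalized area).

## 5. Problem sizes used by the tests and acceptance script

The unit suite uses shortened channel domains (0.6–1.2 mm) at 4–5 µm cells
and small acquisition grids (2×2 to 4×2 tiles of 128–256 px); the
acceptance checks run the default 2.2 mm domain at 2.5 µm cells, the full
13×3×18 noiseless channel for recovery/streaming equality, reduced 4×2×5
channels (30 nodules) for the six-dose survival-fraction recovery, and
2000 null simulations for the type-I-error calibration. These sizes are the
package's chosen defaults for a laptop-scale reproduction; all of them are
configurable upward.
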
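# Methods

`lungstrain` quantifies regional volumetric lung strain from paired thoracic
CT volumes acquired at two ventilation states per condition: end-expiration
(EE) and end-inspiration (EI), each at zero (ZEEP) and positive (PEEP)
end-expiratory pressure. This note records the models, the numerical choices,
and what the synthetic validation does and does not establish.

## Strain model

Global strains are volume ratios of segmented lung volumes:

```
LS_STATIC  = (EELV_PEEP - EELV_ZEEP) / EELV_ZEEP x 100
LS_DYNAMIC = (EILV - EELV) / EELV x 100          (within one condition)
LS_TOTAL   = LS_STATIC + LS_DYNAMIC
```

Static strain at ZEEP is zero by convention: end-expiration at ZEEP is the
reference (assumed stress-free) configuration.

Regionally, the same quantity is the local relative volume change of a tissue
parcel: with u the displacement field mapping reference points to their
deformed positions and F = I + grad u, the volumetric strain is
(det F − 1) × 100. This choice — rather than a tensor norm — makes the
regional measure reduce exactly to the global volume-ratio definition when
averaged over the lung (the mean of det F over the reference lung equals the
deformed/reference volume ratio). The total regional strain is defined
additively, TOTAL = STATIC + DYNAMIC, after resampling the PEEP-referenced
dynamic map into the EE-ZEEP frame through the static displacement field.
Exact kinematic composition is multiplicative
(J_total = J_dynamic∘static × J_static); the additive definition ignores the
cross term. For the strain magnitudes involved (static ≈ 30–55%, dynamic ≈
10–40%) the discrepancy is a few strain points and is quantified by the
frame-additivity test in the suite. ROI summaries of the dynamic component
alone are reported in each condition's own frame; only the TOTAL composition
requires the common frame.

Both aggregation orders (voxelwise sum then ROI average, vs ROI averages
summed) are available; they agree except through the ROI-mask nonlinearity,
and the pipeline reports the voxelwise-sum-first variant.

## Segmentation and volumes

Lungs are segmented by HU thresholding on the closed interval [−1000, −50],
followed by connected-component filtering (components touching the volume
boundary are extrathoracic air and are dropped; the two largest remaining
components are kept), optional morphological closing (default radius
1 voxel) to absorb vessel-sized holes, and left/right labelling by centroid
on the left-right axis. Lungs merged at the midline are split by a single
erosion–relabel–regrow pass. Volumes are voxel counts × voxel volume.
Trachea and main bronchi are not excluded; an air-filled bronchus inflates
the hyperaerated compartment of the ROIs it crosses, and the phantom can
reproduce that artifact on demand.

## Registration

Deformable registration uses a multi-resolution cubic B-spline free-form
deformation (SimpleITK), optimised with regular-step gradient descent under
physical-shift parameter scaling — chosen because it is monotone in the
metric and stable across B-spline grid refinements, where adaptive
learning-rate estimation oscillates and ITK's L-BFGS-B rejects multi-level
grids outright. The returned field u lives on the reference (EE) voxel grid,
in mm, such that resampling the moving image at x + u(x) reproduces the
fixed image; strain is therefore Lagrangian on the reference configuration.

Two defaults differ from common first guesses and were set by phantom
experiments:

* **Metric: local (neighbourhood) normalized cross-correlation (LNCC,
  radius 3 voxels).** Inflation changes lung HU: if only gas enters a
  parcel, HU_moving = −1000 + (HU_fixed + 1000)/J, a spatially varying
  affine intensity map. Plain SSD is minimised by an intensity-matching
  warp, not the material warp — on phantoms it converges confidently to the
  wrong correspondence. LNCC is invariant to locally affine intensity
  changes and recovers the material warp. SSD, global NCC and Mattes mutual
  information remain selectable.
* **Control-point spacing: 48 mm at the finest level** (about a quarter of a
  dog-thorax field of view), not a few voxels. Tidal deformation varies over
  centimetres; a finer control grid mostly fits noise, which the strain — a
  derivative of the field — amplifies. On analytic phantoms a 16 mm grid
  doubles the regional strain error relative to the 48 mm grid.

Remaining defaults: 3 pyramid levels (shrink 4/2/1, smoothing 2/1/0),
60 iterations per level, initial step 6 mm halving (factor 0.6) to 0.02 mm,
full metric sampling. Full sampling makes the result bitwise deterministic;
seeded random sampling is available but was not faster at equal accuracy in
our benchmarks. Smoothness is controlled by the B-spline grid scale rather
than an explicit bending-energy penalty (the SimpleITK registration method
does not expose one). Externally computed displacement fields can be loaded
from 4D NIfTI and drive the strain pipeline unchanged.

## Strain recovery

Per-voxel deformation gradients use central differences of u scaled by the
physical spacing. The raw Jacobian field is projected onto a regular
hexahedral mesh with trilinear elements (default node spacing 8 mm;
16 mm for the coarse phantom studies): 2×2×2 Gauss points per element sample
the voxel Jacobian strain, nodes take the lumped-mass (shape-function
weighted) average over elements containing lung tissue, and the voxel map is
the trilinear back-interpolation, NaN outside the lung. On analytic fields
(uniform scale, shear, radial, graded) the recovered strain matches the
closed form to < 0.5 strain points mean and < 2 max at 96³/2 mm with 4 mm
nodes. Non-positive Jacobians on more than 1% of lung voxels raise a
warning with the count.

## Aeration

Gas fraction is the standard linear HU relation gf = clamp(−HU/1000, 0, 1).
Compartments follow the conventional CT ranges, closed on each printed
bound: hyperaerated [−1000, −901], normoaerated [−900, −501], poorly
aerated [−500, −101], non-aerated [−100, +100]; lung voxels outside the span
clamp into the nearest class, so the four classes always partition the lung.
Classification is voxelwise (nodal aggregation is available through the ROI
machinery); the partition-of-unity and delta-conservation identities hold
either way.

## ROI grid and statistics

Each lung is cut by 9 apicobasal and 9 dorsoventral planes into a 10×10
grid; plane positions are chosen by dynamic programming to minimise the
worst deviation of any slab from 10% of the lung tissue volume (voxel count
× voxel volume by default; an optional per-voxel weight, e.g. 1 − gas
fraction, supports density-weighted partitions). Cells without lung tissue
are flagged missing and excluded from quadrant means and tests. Quadrants
are the four 5×5 blocks (apical = rows 1–5, ventral = columns 1–5). Grids
are rebuilt per ventilation state and matched by (i, j) index across states,
mirroring positional comparison of per-state maps; left and right lungs are
partitioned separately, with tissue-weighted pooling into one per-subject
array for group analysis.

ZEEP-vs-PEEP ROI comparisons use per-ROI paired t tests across subjects with
Bonferroni correction over the number of ROIs actually tested (significance
at adjusted p < 0.05) — a deliberate simplification of repeated-measures
ANOVA, whose factor structure adds nothing to per-ROI paired contrasts here.
The association between static strain and aeration change uses Pearson
correlation over pooled non-missing ROIs.

## Capnography

Volumetric capnograms are analysed on the expired-volume axis (volume by
trapezoidal integration of flow), so flow irregularities do not bias the
mixing integrals. Phase III is the longest terminal segment whose linear fit
has residual SD below 1 mmHg (config-exposed), spans at least 30% of the
expired volume, and lies above 5 mmHg (rejecting CO2-free traces); the start
is then refined by trimming while the segment head deviates systematically
from the refit, which stops the fit from swallowing the tail of the phase-II
front. For breaths with dead-space fractions near 0.7 the plateau is
genuinely shorter than 30% and the minimum span must be relaxed by the
caller. PACO2 is the phase-III fit at its volume midpoint; PECO2 is the
volume-weighted mean expired CO2; Bohr dead space is
(PACO2 − PECO2)/PACO2. Driving pressure is Pplat − total PEEP and static
compliance VT over that; total PEEP at ZEEP defaults to 0 unless an
end-expiratory pause pressure is supplied.

## Synthetic data: what it emulates, and what it does not

The phantom is a supine dog thorax: an elliptic soft-tissue body (40 HU),
two ellipsoidal lung fields (default semi-axes 62×48×26 mm) with a linear
dorsoventral HU ramp (−900 ventral to −300 dorsal — the gravitational
aeration gradient), an optional air-filled bronchial tube (the hyperaeration
artifact), a smooth material texture field (Gaussian random field, SD 60 HU,
10 mm correlation length) standing in for vascular/parenchymal density
variation, and i.i.d. Gaussian acquisition noise (SD 5 HU, fresh per state).
The texture is essential, not cosmetic: without it a ramp-only lung gives
intensity-based registration no usable signal (aperture problem, compounded
by the gas-rescaling ambiguity above).

Deformed states are rendered analytically — each voxel of a warped state is
evaluated through the warp's exact inverse, with lung HU rescaled under
tissue conservation (1 − gf_new = (1 − gf_old)/det F) — rather than by
resampling the reference image. Resampling would give warped states a
partial-volume shell that the sharp reference lacks, biasing segmented
volume ratios by several percent at coarse voxel sizes; analytic rendering
keeps all four states statistically identical at the boundary, so segmented
volume ratios converge to the warp's Jacobian integral. Expected
aeration-class volumes account for texture and noise by Gaussian smearing of
the thresholds (an error-function quadrature against the ellipsoid
cross-section), computed independently of the classification code.

Analytic warps expose displacement, exact Jacobian and exact inverse:
translation, per-axis affine scaling, radial inflation
(r → r(1 + β e^(−r²/2σ²))), and the graded dorsoventral stretch with
volumetric strain linear in the dorsoventral coordinate — in a uniaxial
variant (all strain along one axis) and an isotropic variant (each axis
stretched by (1+ε)^⅓, det F = 1 + ε exactly) that keeps chest-wall
displacement physical at high volumetric strain. Default study conditions
for simulated cohorts follow the in-vivo ranges: static strain graded
35–55%, dynamic 25–40% at ZEEP and 12–33% at PEEP, ±3 points per-subject
jitter, six subjects.

Capnogram generation is piecewise with closed-form truths: CO2-free phase I,
a cubic-smoothstep phase II (polynomially integrable), linear phase III;
PACO2, PECO2 and the Bohr fraction follow in closed form from the same
pieces.

Passing these suites shows the pipeline recovers known smooth deformation
and aeration structure under realistic noise. It does not establish accuracy
on real thoraces: real lungs have airway trees, cardiac motion, sliding at
the pleura, reconstruction artifacts, and deformation at spatial scales the
default 48 mm control grid cannot represent. In particular, localized
deformations whose displacement stays below about half a voxel are not
recoverable by the default configuration even when their strain is large
(sub-voxel radial "bumps" fail exactly this way), and the suite's
registration targets therefore use the smooth graded warps that match the
deformation scale the method is built for.

## Problem sizes and runtimes

Validation phantoms are 48³ voxels at 4 mm (registration studies; one
registration ≈ 1.5–2 min on one core) and 96³ at 2 mm (strain-recovery
oracle, aeration geometry). Simulated cohorts for orchestration tests are
40³ at 4.8 mm with the generator's exact fields standing in for the
optimizer, which the pipeline supports as an explicit bypass. These sizes
were chosen as the smallest that leave ≥ 10 voxels across each lung axis for
the 10×10 grid and keep boundary effects below the stated tolerances.

## Known limitations

* Additive TOTAL under-counts the multiplicative cross term (quantified,
  a few strain points at study magnitudes).
* Registration accuracy is validated by parameter recovery on phantoms, not
  against an independent in-vivo gold standard (none exists for regional
  strain).
* The ROI grid's cross-state correspondence is positional, not material: an
  (i, j) cell at ZEEP and at PEEP are the same *relative* location, not the
  same tissue.
* Aeration compartment thresholds are the conventional literature values and
  config-exposed; HU calibration drift in real scanners is not modelled.
* Phase-III detection assumes a plateau-like terminal segment; breaths with
  severe phase-III curvature (e.g. obstructive disease) need the residual
  tolerance raised.
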
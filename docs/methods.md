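# Methods

`ras1zone` simulates the dynamics of the fission-yeast Ras1 polarity
patch during mating: a reaction–diffusion system for active Ras1
(Ras1-GTP), inactive Ras1 (Ras1-GDP) and the GTPase-activating protein
Gap1 on a closed, curved membrane surface, with an autocatalytic
GEF-mediated positive feedback and a delayed Gap1 negative feedback.
This note records the model, the numerical choices, and what the tests
do and do not establish.

## Membrane geometry and discretization

The cell membrane is a spherocylinder: a cylinder of radius r = 2 μm
with hemispherical caps, tip-to-tip length 6 μm for mating cells
(volume 58.6 μm³, area 24π ≈ 75.4 μm²) and ~11 μm for interphase cells
used in FRAP work.  The surface is tiled with Voronoi polygons whose
generators sit on `n_axial` rings placed at equal increments of
cumulative meridian *area* (on a spherocylinder this is equal spacing in
the axial coordinate), with a constant `n_circ` generators per ring and
alternate rings staggered by half a step.  With the default 45 × 40
layout every polygon has area ≈ 75.4/1800 ≈ 0.042 μm², within the
working range 0.017–0.046 μm²; the polar band is tiled by its own
ring's polygons, so no pole point is needed.

Each generator's Voronoi cell is computed in a local tangent chart
(direction by orthogonal projection onto the tangent plane, magnitude by
3D chord length, which is a near-isometry at the ~0.2 μm generator
spacing against the 2 μm curvature radius), using `scipy.spatial.Voronoi`
on the ~48 nearest candidates plus a guard ring.  The
Laplace–Beltrami operator is a finite-volume two-point flux per shared
Voronoi edge,

    (L f)_i = (1/a_i) Σ_j g_ij (f_j − f_i),   g_ij = ℓ_ij / d_ij,

with edge length ℓ and generator distance d measured in the chart and
g symmetrized between the two charts of an edge.  Symmetry makes the
operator exactly conservative (Σ a_i (Lf)_i = 0 to rounding) and exact
on constants.  Validation: a point source diffused on the cylindrical
section (which is intrinsically flat) matches the planar Gaussian heat
kernel to < 0.5% L2 error, and a 2× refinement changes a 10-s diffusion
profile by well under 2%.

For the tip-curvature study the caps become half-spheroids with polar
curvature radius `tip_radius` (equatorial radius fixed at r, tangent
join to the cylinder); the cylinder length absorbs the cap-area change
so total area is held fixed.

## Reaction–diffusion model

Membrane surface densities C_RT (Ras1-GTP), C_RD (Ras1-GDP) and C_GAP
(Gap1), all in μm⁻²:

    ∂C_RT/∂t = D_RT ΔS C_RT + (k0p C_GEF + r_noise) C_RD
               − (k1n + k2n C_GAP) C_RT − r_RT C_RT
    ∂C_RD/∂t = D_RD ΔS C_RD + j_RDp + (k1n + k2n C_GAP) C_RT
               − (k0p C_GEF + r_noise) C_RD − r_RD C_RD
    ∂C_GAP/∂t = D_GAP ΔS C_GAP + k3n C_RT^h/(C_sat^h + C_RT^h)
                − r_GAP C_GAP

The GEF (Ste6) forms a finite cytoplasmic pool E_ctot = 100 molecules in
quasi-static equilibrium with Ras1-GTP, with linear and quadratic
recruitment weights:

    C_GEF = (k1p C_RT + k2p C_RT²) E_c / V
    E_c   = E_ctot / (1 + ∫ (k1p C_RT + k2p C_RT²)/V da)

so E_c + ∫ C_GEF da = E_ctot holds exactly by construction.  The
quadratic term makes GEF capture winner-take-all: a region rich in
Ras1-GTP drains the pool from the rest of the cortex.  Gap1 provides the
delayed negative feedback: recruited with Hill cooperativity (h = 2,
half-saturation C_sat = 60 μm⁻²), it spreads laterally (D_GAP = 0.2
μm²/s, faster than D_RT = 0.04 μm²/s) and hydrolyzes Ras1-GTP.

Default rate constants (the mating-cell set): D_RT 0.04, D_RD 0.15,
D_GAP 0.2 μm²/s; r_RT 0.02, r_RD 0.001, r_GAP 0.1 s⁻¹; k0p 0.02 μm²/s;
k1p 5 μm³; k2p 1000 μm⁵; k1n 0.002 s⁻¹; k2n 0.1 μm²/s; k3n 100
μm⁻²s⁻¹; j_RDp = r_RD × 38 = 0.038 μm⁻²s⁻¹; r_noise 0.002 s⁻¹.  The
diffusion coefficients and membrane dissociation rates are the values
calibrated by FRAP (below); the feedback constants are the documented
defaults of the model.

### Activation noise

Random background activation converts Ras1-GDP to Ras1-GTP cell by
cell: per step and Voronoi cell, dN = dt · da · p · r_noise · C_RD with
p uniform in [0, 1).  The whole-cell scale r_noise · C_RD · S ≈ 5.7 ≈ 6
molecules/s is the documented calibration; note the uniform p has mean
1/2, so the realized mean activation flux is half that scale.  Both
facts are kept as stated; the per-step draw follows the formula.  The
noise is defined relative to the fixed dt (multiplicative noise tied to
the integration step), so dt is not adaptive.

### Integration

Explicit forward Euler at dt = 0.01 s on the 45 × 40 mesh (the
explicit-Euler bound for D = 0.2 μm²/s on this mesh is ≈ 0.011 s; a
`StabilityError` is raised when violated).  Negative densities produced
by the noise or stiff reactions are clipped to zero and the clipped
mass is logged; it stays below 0.1% of total mass in the tested
regimes.  Initialization: C_RD = j_RDp/r_RD with ±5% uniform per-cell
fluctuation, C_RT uniform-random in [0, 0.01·C_RD], C_GAP = 0 (the
fluctuation magnitudes are config fields).  The compiled integrator was
verified against an independent `scipy.integrate.solve_ivp` (RK45,
rtol 1e-7) integration of the same right-hand side to 0.2% final-state
agreement, and the single-step reference implementation in numpy is
asserted equal to the compiled kernel in the test-suite.

### Explicit-GEF variant

The expanded model promotes the GEF to a fourth field with recruitment
rates ρ1 = k1p·r_GEF, ρ2 = k2p·r_GEF and dissociation r_GEF, D_GEF =
D_RT, and E_c = E_ctot − ∫C_GEF da.  It requires dt = 1e-5 s.  For
r_GEF → large the explicit field converges to the quasi-static
equilibrium (measured deviation ~2%/r_GEF·1000, i.e. < 1% at r_GEF =
5000 s⁻¹).  Full-mesh runs at dt = 1e-5 are hours-scale; the packaged
scaled variant runs on a 2×-coarsened (23 × 20) mesh.

## FRAP machinery

Two linear transport models: uniform exchange (∂C/∂t = D ΔS C + j⁺ −
rC) for cortex-wide species, and Gaussian tip recruitment (source
A/(2πσ²)·exp(−d²/2σ²) with d the arc distance to the tip; σ = 0.4 μm
for the mating focus, 0.8 μm for vegetative Gap1).  Bleaching zeroes the
field on the bleach mask; for recruitment protocols the amplitude is
multiplied by a recovery factor at bleach (0.5 full-focus, 0.7
half-tip), so linearity forces the long-time recovery to that factor —
reproduced by simulation to < 0.1%.  Readout emulates a confocal slab
(cells within 0.6 μm of the medial plane, unweighted mean), and traces
are normalized to the pre-bleach mean.  Side bleaches span half the
circumference (6.28 μm at r = 2 μm) and an axial width of 1.5 or 4 μm.
Photobleach correction divides background-subtracted intensities by
exp(−r_PB t) with r_PB least-squares fitted to the background-subtracted
cytosolic trace.

Fitting is a (D, r) grid search (default steps 0.01 μm²/s and 0.005
s⁻¹) over joint small- and large-strip traces; the acceptable set holds
the grid points whose curves stay inside the traces' SD band at every
frame (the pointwise policy is a flag), and the best point minimizes
the summed squared residuals.  Parameter recovery on noisy synthetic
traces (5% frame noise) lands within one grid step of the truth in ≥
90% of replicates.

Validation of the transport code: full-circumference strip bleaches on
a long (16 μm) mesh match a 1D diffusion oracle (erf solution for an
indicator bleach, evaluated at the realized mask width — centroid
membership quantizes the strip to whole generator rings) to < 1%.

## Patch analytics

On-mesh detection: a discrete patch exists when the spatial max of
C_RT exceeds 5× its median and an absolute floor of 1 μm⁻²; member
cells lie above 25% of the max, grouped by connected components.  These
thresholds are a config object.  Patches are linked across frames by
member-cell overlap into episodes (birth, peak, death).  Two period
readouts exist: peak-to-peak intervals of the spatial-max series
(prominence ≥ 50% of the post-burn-in range), and the episode record.
Recurrent "appearance and disappearance" is scored as re-formation: a
new episode begins after an earlier one has ended.  Re-formations are
counted from 150 s onward — during the first minutes the random initial
condition sorts itself out, and those settling events occur once even
in the quiescent low-noise regime — and a noise level is said to
support cycling when any replicate shows at least two of them.  The distinction
matters because during a relocation the successor patch often starts
growing before the old one has decayed, so the spatial max does not
dip; episode tracking still registers the event.

Axial profiles average densities over a 0.2-μm strip along the long
axis through a chosen cell, one value per generator ring (the strip is
widened per ring to the local generator spacing so every ring
contributes); FWHM is measured after subtracting the 25th-percentile
baseline.  The experimental-style 1D quantification applies the
image-analysis rules: runs of ≥ 2 pixels (0.13 μm each) above
background qualify as patches when their mean exceeds background + 3
SD, and qualifying regions closer than 0.26 μm merge (gap included in
the merged size).

Regime classification is rule-based: uniform activation (> 95% active
area) vs no-patch (activity at or below the noise floor) vs cycling
(re-forming episodes; single / occasional-two / multiple by the mean
count of substantial simultaneous patches, i.e. components within 50%
of the frame's peak) vs persistent states (stable single patch,
one-cell minimum-size patch, traveling wave when the surviving patch
drifts > 0.05 μm/s without dying).

## Study conditions and problem sizes

The packaged experiment battery (shared by the tests and the
acceptance script) uses the reference 45 × 40 mesh and the default
parameter set: 600-s runs (up to eight seeds, intervals pooled) for the exploration period and
far-field Ras1-GDP average; 600-s runs, two seeds per value, for the
geometric bisection of the activation-noise window; 800-s runs, three
seeds, for the downward Gap1-detachment sweep (0.1 … 0.04 s⁻¹); 400-s
deterministic runs for the FRAP recovery levels; and 120-s runs on the
2×-coarsened mesh for the explicit-GEF variant.

## Known limitations

* With the documented rate constants, membrane Ras1 is not in
  stationary balance at C_RD = 38 μm⁻²: background activation (noise
  plus residual GEF) routes Ras1 through the GTP state, which
  dissociates 20× faster than the GDP state, while the recruitment flux
  is fixed at j_RDp = r_RD·38.  Far-field C_RD therefore decays from its
  initial 38 to ≈ 25 μm⁻² over 600 s (time average ≈ 30).  The value 38
  is the calibration input, not a sustainable long-run average.
* Related, the late phase of long runs (drained Ras1 pool) favors
  slowly competing coexisting patches over clean single-patch cycling;
  roughly half the seeds settle into a persistent patch or a two-patch
  standoff within 600 s.  Exploration-period estimates pool inter-peak
  intervals across seeds for this reason.
* On the 2×-coarsened mesh each polygon is 4× larger, so per-cell
  activation noise is coarser; both model variants then favor several
  coexisting patches, and the explicit-GEF cycling-period check on that
  mesh inherits this bias.
* The synthetic FRAP fixtures add i.i.d. Gaussian frame noise; real
  traces have correlated acquisition noise, drift and registration
  error, so passing recovery tests demonstrate correctness of the
  fitting machinery, not robustness to real-microscopy artifacts.
* Cytoplasmic pools are uniform and constant (no cytoplasmic
  gradients), the geometry is static (no shmoo outgrowth), and the
  Cdc42/actin/MAPK layers are outside the model.
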
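# Methods

`myowalk` synthesises diffusion tensor cardiovascular MR (DT-CMR)
signals by Monte Carlo random walks of water molecules through a
virtual cardiac microstructure. This note records the model, its
assumptions, the defaults and why they were chosen, the numerical
policies, and what the synthetic substrates do and do not represent.

## Tissue model

The substrate is built from one **building block** — a 3-D arrangement
of impermeable cell-shaped obstacles — replicated to fill (and pad
beyond) an imaging voxel of 2.8 × 2.8 × 8.0 mm³.

**Histology-style blocks.** A 2-D label raster emulating a transverse
histology section (see *Synthetic histology* below) is polygonised:
each cell's pixel boundary is traced exactly along pixel edges, so the
polygon area equals the pixel count times the pixel area, then
simplified by Douglas–Peucker with the tolerance capped at 0.45 px so
that polygons of cells separated by at least one pixel can never
overlap. Footprints are extruded along the cell axis (z′) into closed
triangulated prisms with lengths drawn uniformly from 114–126 μm — the
reported range of cardiomyocyte lengths — and a uniform axial offset
inside the block depth (the maximum cell length, plus twice the
sinusoid amplitude when one is used, so the displaced mesh can never
leave the periodic tile). The uncovered axial ends are extra-cellular
gaps standing in for intercalated discs; membranes have zero thickness
and are impermeable. A sinusoidal z′-displacement of all mesh
vertices, amplitude 5 μm and wavelength equal to the block width
(500 μm by default), staggers cell ends as a function of x′. The
amplitude and wavelength are free choices (no published values exist):
the wavelength must divide the block width so the displacement is
identical in every tile and one canonical mesh serves all of them;
5 μm is enough to break the straight x′ channels without perceptibly
distorting cell volumes (the displacement is a pure shear, so volumes
are preserved exactly). For many-cell blocks the prism side walls are
tessellated into ≤ 15 μm axial rings — the surfaces are unchanged, but
short triangles keep the bounding-volume hierarchy spatially tight
(full-length wall triangles overlap every axial position and degrade
ray queries by two orders of magnitude).

**Idealised cuboid blocks.** A single square-section cuboid with side
√(mean cell area) (default √110 ≈ 10.5 μm) and length 120 μm (the
mid-range cell length), separated from its periodic neighbours by one
gap g applied both laterally and axially. g is solved by bisection of
the closed-form volume fraction ECV(g) = 1 − s²L/((s+g)²(L+g)); the
achieved extra-cellular volume fraction (ECV) is within 0.1 percentage
points of the target for all ten study targets in 16–41 %.

**Lattice.** Blocks tile the plane transverse to the transmural (y)
axis, with every other x′ column shifted by half a block in z′ to
eliminate long straight extra-cellular channels along the cell axis.
Blocks stack transmurally with a rotation of 10°/mm about y — the
linear helix-angle progression of myocytes (4° per 400 μm histology
block, a 24° orientation span across seven layers of a 2.8 mm voxel).
Cells lie strictly inside their block, so layer boundaries never cut
membranes. The global→canonical coordinate map (rotate by the layer
angle, un-stagger, fold modulo the block extents) is an exact
bijection; round-trip error is below 10⁻⁹ μm for 10⁵ random points in
the tests.

## Synthetic histology

No real histology segmentation ships with the package. The generator
(`synthesize_histology`) emulates the salient structure of a manually
segmented porcine mid-ventricular section: a 500 × 400 μm region at
0.5 μm/px containing ~1.1 × 10³ polygonal cell cross-sections of mean
area ~110 μm², grouped into 12 horizontal sheetlet bands separated by
~2 μm collagen shear-layer strips that cells may never enter. Cells
are Voronoi regions of well-spread (best-candidate) seeds within each
band, eroded until the target extra-cellular area fraction (default
38 %, the value estimated from thresholded histology) is met. One full
erosion pass is mandatory, so every pair of cells is separated by at
least two pixels; the remaining erosion is distributed across cells
with strongly skewed random weights, because the extra-cellular space
of real myocardium is non-uniform — wide pools beside thin clefts —
and that heterogeneity is precisely what makes the thickened and
shrunk morphs of the same tissue physically different. The generator
is deterministic given its seed.

What this emulates: realistic cross-section size dispersion, sheetlet
banding, shear layers, non-uniform inter-cellular gap widths. What it
does not: true cell shape irregularity (histology cells are more
concave), intra-sheetlet branching, 3-D sheetlet curvature, and the
specific gap-size distribution of any real section. Consequently,
passing tests on these substrates demonstrate correct *mechanics* and
reproduce *directions* of published effects (e.g. shrunk versus
thickened morphologies), not the magnitudes measured on real pig
histology, which depend on that section's geometry.

## Morphing

`thicken_cells` grows every cell one boundary ring per iteration; an
extra-cellular pixel is claimed only if it is 4-adjacent to the
claiming cell, outside the shear mask, and has no 8-neighbour of a
different cell — so cells stop at a one-pixel gap. When two cells grow
into an even-width gap they can claim adjacent pixels in the same
sweep; such conflicts are resolved deterministically in favour of the
lower cell id, which preserves the one-pixel-gap invariant (verified by
exhaustive scan) while still closing gaps completely. `shrink_cells`
erodes every cell boundary (4-connectivity) with two guards: a cell is
never annihilated (its pixel nearest the centroid survives) and never
split (the largest connected component survives). Thickening stalls
progressively as narrow gaps lock while shrinking widens all gaps at
once, so traversing the same ECV range takes many thickening passes but
few shrinking passes — the qualitative asymmetry the morphing study
reports. `morph_to_ecv` applies the same rules one cell at a time for
~0.01-percentage-point control when building sweep substrates.

## Pulse sequences

Three simplified encodings are modelled as effective gradient
waveforms starting at the initial 90° pulse and ending at the echo,
with the polarity of everything after the refocusing point already
reversed; RF pulses are instantaneous and imaging gradients are not
simulated.

* **PGSE** — two trapezoids (ramp ε, flat δ), onset-to-onset spacing Δ,
  placed symmetrically about TE/2.
* **STEAM** — the same two-lobe shape with Δ = 1 s bridging the mixing
  time TM (no gradients while the magnetisation is stored); the
  catalogued timings satisfy TM + TE/2 = Δ exactly, so placement is
  symmetric.
* **M2SE** — four trapezoidal lobes with flat-tops (δ₁, δ₂, δ₂, δ₁) and
  alternating effective polarity. The zeroth moment vanishes
  identically; the first lobe's onset and the central gap are solved
  numerically so the first and second moments vanish too
  (velocity/acceleration compensation). The catalogued 40 mT/m column
  admits an exact solution (residuals ~10⁻¹⁰ relative, and the
  resulting b is 450 s/mm², confirming the reconstruction); the
  80 mT/m column does not fit any moment-nulled four-lobe placement
  inside its TE — that TE evidently contains vendor hardware intervals
  the simplified model omits. `build_waveform` then either raises
  (default) or, with `allow_residual=True`, uses the minimum-residual
  placement; since the virtual tissue is static, residual motion
  moments have no effect on the simulated signal, so the G_max
  comparison uses the fallback.

Diffusion gradients drive two scanner axes at once: each of the six
encoding directions has two components of magnitude 1/√2, giving total
gradient √2·G_max with each physical axis at G_max. Units are
μm/ms/mT·m⁻¹ internally with γ = 2.6752×10⁸ rad s⁻¹ T⁻¹; b-values are
reported in s/mm². b and the full 3×3 b-matrix come from
q(t) = γ∫G dt accumulated exactly over the piecewise-linear waveform
and Simpson quadrature of ∫qqᵀdt on a 0.01 ms grid (error ≪ 0.01 %).
The catalogued PGSE and STEAM timings reproduce b = 450 s/mm² within
0.1 %, which fixes the Δ convention (onset-to-onset) and confirms the
published "450 m/ms²" as a typographical variant of s/mm².

Discretisation: timesteps are capped at 0.1 ms while any gradient is
on and 1 ms otherwise; trapezoid corners are always grid points; the
largest intervals are halved until at least N_T = 10³ steps remain.

## Random walk

Each of N_P particles (default 10⁴) walks independently. Positions are
seeded uniformly in the voxel padded on every face by √(6·D_max·T) —
the RMS free displacement over the full simulation (134 μm for
D = 3 μm²/ms over the ~1 s STEAM encoding) — so no particle that could
end inside the voxel starts outside the seeded box. The compartment
(cell id or extra-cellular) is assigned once by ray-parity point
location and never changes: membranes are impermeable.

Per timestep dt the particle draws a displacement with components
~N(0, 2Ddt), per-component rejection-resampled beyond ±5σ, where D is
its compartment's diffusivity (defaults D_IC = 1.5, D_EC = 3.0 μm²/ms,
free water at 37 °C for the extra-cellular space). The displacement is
resolved into sub-steps whose lengths sum to the drawn step length:
Möller–Trumbore ray casting over a flat AABB hierarchy of the canonical
block mesh finds the nearest membrane intersection (segments are split
at tile and layer boundaries and mapped to the canonical frame), and
the remaining length is reflected elastically, R′ = R − 2(R·n)n.

Numerical policies: intersections closer than 10⁻⁹ of the segment
length are ignored and the triangle just hit is excluded from the next
query; after a reflection the position is nudged 10⁻⁹ μm off the wall
on the incoming side; intersection ties (shared edges) break on the
lowest triangle index. Reflections per step are capped at 100; an
overrun truncates the step at the last wall and is counted (zero
occurrences at the default step sizes). The accelerated resolver is
bit-compatible with a naive all-triangle reference resolver (tested on
10⁴ random steps).

Phase accrues as φ += γ (G_eff·r̄) dt with r̄ the midpoint of the
step's straight-line chord — second-order quadrature that removes the
first-order bias at the 0.1 ms gradient-on step size. Reproducibility
is a hard contract: every particle owns a counter-based (splitmix64)
RNG stream derived from the master seed and its index, so results are
bitwise identical regardless of thread count or execution order.

The engine was validated against the exact reflecting-plates
propagator: for axial encoding of particles confined to a 120 μm cell,
the simulated attenuation matches the eigenfunction-series value to
0.2 % (A = 0.841 vs 0.839 for the stimulated echo).

## Signal synthesis and tensor analysis

Only particles whose final position lies in the voxel contribute.
The attenuation is the real part of the phasor mean, A = Re⟨e^(−iφ)⟩
(the imaginary part is antisymmetric noise, kept as a diagnostic; a
magnitude estimator would bias upward at low particle counts). The
b = 0 reference is analytically 1, so the tensor follows from the
unweighted linear inversion of ln A_k = −B_k : D over the six
directions using full numeric b-matrices — cross-terms of the two-axis
scheme are handled exactly, with no intercept to fit. Eigenvalues are
sorted descending; MD, FA and tensor mode (3√6·det of the
Frobenius-normalised deviatoric tensor, clipped to [−1, 1]) use the
standard closed forms. Compartment-resolved tensors repeat the same
pipeline on intra-only and extra-only in-voxel particles.

Across realisations (default 10) scalar metrics are summarised by the
sample median with the order-statistic confidence interval whose
binomial coverage is nearest 95 % (ranks 2 and 9 at R = 10, coverage
97.9 %). Eigenvector uncertainty uses the cone-of-uncertainty
construction for antipodally symmetric axes: the mean orientation is
the principal eigenvector of the mean dyadic tensor ⟨EEᵀ⟩ (insensitive
to sign flips) and the cone half-angle is the 95th percentile of the
angles between realisations and that mean, capped at 90°.

## Known limitations and observed deviations

* **Axial restriction of the idealised substrate.** With impermeable
  caps at both ends of every 120 μm cell, intra-cellular water is
  confined axially. Reflected-diffusion theory (slowest relaxation
  time τ = L²/π²D ≈ 0.97 s for L = 120 μm, D = 1.5 μm²/ms) then fixes
  the apparent axial diffusivity: ~1.39 μm²/ms for the spin echo
  (diffusion time ~17 ms) and ~0.78 μm²/ms for the stimulated echo
  (Δ = 1 s ≈ τ). The simulator reproduces these values to well within
  Monte Carlo error, and the acceptance runs report them: PGSE
  compartment fits give λ1 ≈ 2.79 (extra) and ≈ 1.39 (intra), and the
  STEAM intra-cellular offset is ≈ −0.73 μm²/ms. Simulations in the
  literature built on real-histology substrates report near-exact
  PGSE recovery of both diffusivities and a STEAM offset of
  only ≈ −0.2; inverting the propagator series shows such values
  require an effective axial confinement length of 350–450 μm, several
  cell lengths, i.e. an axially connected intra-cellular space. A
  virtual tissue with fully capped cells is the physiologically
  conservative choice (intercalated discs are real barriers), but
  users comparing against data where myocyte ends appear transparent
  should treat the axial restriction as a model *choice* with the
  quantitative consequences above.
* The extra-cellular λ1 deficit (~5 %) comes mostly from the ~4 % of
  extra-cellular volume trapped in the thin slabs between axial cell
  ends, plus the 28° transmural fan of orientations across the voxel.
* Membrane permeability, perfusion/microvasculature, relaxation
  weighting, noise, cardiac motion and strain are all outside the
  model.
* The M2SE 80 mT/m encoding is not exactly moment-nulled (see above);
  its b-value additionally depends on the inter-lobe gaps, so no
  quantitative claim is attached to it beyond refocusing.

## Problem sizes

Defaults mirror the study conditions: N_P = 10⁴ particles, N_T ≥ 10³
timesteps, 10 realisations. The bundled acceptance and test runs use
reduced sizes chosen once as adequate for their statistical bands:
three seeds of 10⁴ particles for compartment recovery, a six-point
cuboid ECV sweep with three realisations of 3×10³ particles, and
200 × 160 μm four-sheetlet synthetic histology for the
ECS-distribution comparisons — probed with STEAM, whose ~1 s mixing
time is the only encoding that resolves the thickened/shrunk
difference above Monte Carlo noise at that reduced size (the 17 ms
spin-echo diffusion time barely samples the gap network).
`ExperimentPlan(scale=...)` scales particle counts and realisation
numbers without touching the physics.
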
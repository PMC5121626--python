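# Methods

## The measurement being modeled

A voxel of brain tissue contains a network of microvessels whose blood
differs in magnetic susceptibility from the surrounding tissue. In a
gradient-echo-sampled FID + spin-echo (GESFIDE) acquisition the
susceptibility-induced mesoscopic field gradients dephase water spins; the
degree and time course of that dephasing — and of its partial refocusing by
the 180° pulse — carry information about the blood volume fraction (BVf),
the vessel radius distribution, and the blood oxygen saturation (StO₂,
which sets the blood–tissue susceptibility difference). Injecting a USPIO
contrast agent raises the intravascular susceptibility by a large, known
offset and repeats the measurement.

The per-voxel *fingerprint* is the echo-wise ratio of the post- to
pre-contrast magnitudes (last eight echoes discarded for SNR). The ratio
divides out every multiplicative factor shared by the two acquisitions —
macroscopic B0 inhomogeneity, B1, and microscopic T₂ decay — leaving only
the susceptibility-driven mesoscopic dephasing. Fingerprints are matched
against a dictionary of simulated fingerprints indexed by
(BVf, radius, Δχ/StO₂, ADC, orientation); the winning entry's parameters
become the voxel's parametric-map values.

## Voxel-scale simulation

**Geometry.** The voxel is a 2D periodic lattice (default 256 × 256 points)
containing circular cross-sections of straight cylinders. For microvessel
networks, 96 equal-radius vessels are placed uniformly at random with
periodic wrap-around, rejection-sampled so disks never overlap (10,000
attempts per vessel, then a geometry-infeasible error naming the offending
BVf/radius pair — silent overlap would bias the realized BVf). The physical
voxel side is derived from the blood-volume constraint,
L = √(n·π·r²/BVf). Each vessel draws an independent orientation θ to B0
with cos θ uniform on [0, 1] (isotropic on the hemisphere) and a uniform
in-plane azimuth; cross-sections are kept circular, ignoring the
ellipticity of oblique sections. Large-vessel voxels contain exactly two
parallel cylinders at a prescribed θ. Lattice point (i, j) sits at the
center of cell (i, j) and all distances use the minimum-image convention.

**Field.** The susceptibility difference of the pre-contrast arm follows
Δχ = Δχ₀·Hct·(1 − StO₂) with Δχ₀ = 3.32 ppm (SI) and Hct = 0.42; the
post-contrast arm adds Δχ_USPIO = 3.5 ppm (SI, agent- and field-specific).
The default solver superposes the closed-form infinite-cylinder field —
exterior (γΔχB0/2)·sin²θ·(a/ρ)²·cos 2φ, interior (γΔχB0/6)·(3cos²θ − 1) —
evaluated with minimum-image distances. Inside a vessel only its own
uniform interior value is used. An optional Fourier solver multiplies exact
disk form factors 2πa²·J₁(ka)/(ka) by the in-plane dipole kernel
−½·sin²θ·cos 2(φ_k − φ); it produces the strictly periodic field (replicas
included) and is cross-checked against the closed form near the vessels
(worst-case deviation ≲2% of the local dipole envelope over 2a ≤ ρ ≤ 3a at
k-space oversampling 12; farther out the two differ by the
boundary-condition convention, not by error). The k-space `oversample`
parameter (default 4) controls truncation ringing near vessel surfaces.

**Evolution.** Starting from uniform transverse magnetization after the 90°
pulse, each δt = 0.5 ms step applies phase precession
m ← m·e^{−iωδt} followed by diffusion, implemented as multiplication of the
lattice spectrum by the Gaussian kernel transform exp(−ADC·δt·k²)
(σ = √(2·ADC·δt) per axis; the multiplier is 1 at k = 0, i.e. the kernel
has unit sum and conserves total magnetization). The spectral form is used
rather than a real-space-sampled stencil because the per-step diffusion
length can be far below one lattice spacing (large-vessel voxels span
millimetres), where a sampled 3-point kernel degenerates to a delta. The
180° pulse at SE/2 = 30 ms is ideal and instantaneous (complex
conjugation). Rotation and diffusion are applied sequentially per step; the
splitting error is O(δt²) and invisible at δt = 0.5 ms (the
lattice-resolution test bounds the combined discretization effects at <2%
between 256² and 512²).

**Sampling.** The signal is the lattice mean of m recorded at every step;
echoes (ΔTE = 3.3 ms: eight FID echoes before the pulse, twenty-four from
33.3 ms onward) are sampled by linear interpolation of the complex sum,
then magnitudes are taken — only magnitude data exist in vivo. T₂/T₁ decay
is deliberately absent from the simulator: the fingerprint ratio cancels
it, and phantoms apply it extrinsically to both arms. Intravascular spins
are included and carry the uniform interior field; no separate blood T₂ is
modeled.

## Dictionaries

Preset A spans 42 BVf values (0.25–25%, log-spaced) × 32 radii (0.5–100 μm,
log-spaced) × 29 Δχ values (0–1.4 ppm, linear) at a fixed ADC of
800 μm²/s — 38,976 fingerprints (77,952 individual simulations). Preset B
adds a 27-node linear ADC axis, 500–1800 μm²/s in steps of 50 (containing
the 800 anchor), for 1,052,352 fingerprints. Preset C appends two-vessel
macrovascular voxels: 5 BVf (30–50%) × 8 radii (50–1000 μm, log) ×
6 orientations (0°–90°, even) × 29 Δχ × 14 ADC nodes (every other node of
the B axis), 97,440 additional fingerprints. The original node lists beyond
the printed ranges and cardinalities are not public; the spacings here are
this package's choice and every axis is overridable through `GridSpec`.

One geometry realization (one seed) serves all Δχ/ADC planes of a
(BVf, radius, orientation) cell; per-cell seeds derive deterministically
from the manifest's base seed, so any row regenerates bit-exactly and the
output is byte-identical for any worker count. Dictionaries are stored as
HDF5 (float32 entries, parameter table, JSON manifest with physics,
sequence, grid and seed provenance).

## Matching

Voxel fingerprints are compared to dictionary rows by reduced chi-squared
Σ(fp − row)²/(n − 1) with unit variance weights (no noise map is acquired),
so the ranking equals the sum of squared errors; ties resolve to the lowest
entry index. When the dictionary has an ADC axis, the measured ADC is
rounded to the nearest simulated node (ties toward the lower node) and only
that hyperplane is searched. Goodness of fit is r² = 1 − SS_res/SS_tot
against the selected row; voxels with r² < 0.8 (default), non-positive
pre-contrast signal, or a constant fingerprint (SS_tot = 0) are excluded
from ROI statistics. For in vivo SNR a unit-sum 3 × 3 in-plane Gaussian
(σ = 0.8 voxel, configurable) is applied to both acquisitions before
ratioing; the original σ is not documented, so it is exposed as a
parameter. The ratio orientation defaults to post/pre (the orientation that
produces the spin-echo-shaped rebound) and is configurable; dictionary and
data record the convention in their manifests so a silent mismatch cannot
occur.

## Steady-state comparators

From the same raw signals: ΔR2* is the log-linear slope of ln(pre/post)
over FID echoes 2–8 (echo 1 skipped as transient; the exact windows are not
documented and are configurable), ΔR2 is ln(pre/post)/t at the echo nearest
the spin echo. Then, with susceptibilities in SI units (the familiar 4π
factors of the CGS formulation are absorbed by χ_SI = 4π·χ_CGS):

    BVf = 3·ΔR2* / (γ·B0·Δχ_USPIO)
    VSI = 0.867·√(4π·ADC / (γ·B0·Δχ_USPIO)) · (ΔR2*/ΔR2)^{3/2}

Consistency check built into the tests: the simulator's ΔR2* at BVf = 5%,
r = 5 μm, ADC = 800 μm²/s lands within a few percent of the
static-dephasing plateau BVf·γB0Δχ/3, so the analytic BVf and the
simulation agree by construction, not by fiat. VSI is a weighted mean
vessel size and systematically exceeds the true radius for microvessel
networks (here ≈2× at r = 5 μm), consistent with its definition.

mqBOLD StO₂ fits S(t) = Cte·exp(−t/T₂)·exp(−BVf·(γB0Δχ₀/3)·Hct_micro·
(1 − StO₂)·t) to the multi-gradient-echo decay beyond 10 ms, using the
measured T₂ and BVf maps and the microvascular hematocrit
Hct_micro = 0.42 × 0.85 = 0.357. A log-linear solution seeds a
Levenberg–Marquardt fit; non-convergence or StO₂ outside [0, 1] excludes
the voxel. Two hematocrits deliberately coexist: the systemic 0.42 maps
Δχ ↔ StO₂ for the dictionary axis (so the 1.4 ppm endpoint corresponds to
StO₂ = 0), while 0.357 enters the qBOLD fit. Validity ranges applied at map
level: ADC 0–3500 μm²/s, BVf 0–17%, VSI 0–50 μm, StO₂ 0–100%.

## Digital phantoms

The phantom module replaces the animal cohorts: an image grid partitioned
into bulk tissue, a contralateral "striatum" ellipse and a lesion ellipse,
each carrying one parameter tuple. Defaults follow healthy rat striatum
(BVf 3.5%, r 7.3 μm, StO₂ 82%, ADC 800 μm²/s, T₂ 55 ms); the stroke preset
lowers BVf/StO₂/ADC and enlarges vessels, the tumor preset enlarges vessels
and lowers StO₂ with elevated ADC — the qualitative lesion signatures of
the in vivo literature, snapped onto the target dictionary's axes. Voxel
signals are simulated with the dictionary's own engine, sequence, physics
and seed policy ("exact" mode demands on-axis parameters, so a zero-noise
phantom round-trips pixel-perfectly through matching); exp(−t/T₂) is
applied to both arms, and Gaussian magnitude noise of chosen σ (fraction of
S(0)) is added per echo — Gaussian rather than Rician because the phantoms
operate at SNR ≥ 20 where the two coincide. A multi-gradient-echo series
(15 echoes, ΔTE 4.5 ms) is generated from the qBOLD forward model for
oxygenation-mapping tests.

What the phantoms do *not* emulate: anatomy (no atlas; ellipse ROIs),
partial-volume and motion effects, contrast-agent extravasation, flow,
Rician noise floors at very low SNR, and — most importantly — vascular
geometries outside the simulator's own model class. Passing phantom tests
therefore demonstrates self-consistency of the pipeline and its estimators,
not in vivo accuracy.

## Numerical and design notes

- Simulation of one pre/post pair at 256² takes ~1.4 s on one CPU
  (comparable to the ~2.5 s reported for the original tool); the full
  presets are cluster-scale jobs, so tests and phantom studies run on toy
  grids (3³–5³ tuples) at 64²–128² lattices. The lattice-resolution
  property test bounds the 256²→512² signal change at <2%, and toy-scale
  results transfer for the same reason.
- Echo times do not fall on δt multiples (3.3/0.5); complex-sum linear
  interpolation keeps the printed δt. The refocusing time (30 ms) is an
  exact step multiple.
- Known degeneracy: at very low BVf (≲1%) adjacent Δχ rows are nearly
  indistinguishable — blood oxygenation is weakly encoded when there is
  almost no blood. Recovery studies use toy grids spanning BVf ≥ 2%, and
  the limitation applies equally in vivo.
- At radii ≳10 μm (ADC 800 μm²/s) the sequence enters the static-dephasing
  regime where the FID is radius-insensitive; radius information then comes
  mostly from the spin-echo rebound, which is why the diffusion (ADC) axis
  of presets B/C matters.
- The per-step diffusion σ is validated against a quarter of the voxel
  side; exceeding it raises an error rather than aliasing silently.
- Excluded voxels are carried as masks and NaNs, never dropped from the
  arrays, so ROI statistics and exclusion fractions are reproducible.
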
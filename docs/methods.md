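# Methods

## Model overview

`ectsim` treats current flow through the head during ECT as quasi-static:
the potential obeys ∇·(σ∇V) = 0 with real, purely resistive conductivities,
and fields scale linearly with applied current at fixed σ. Frequency enters
only through the choice of conductivity values: every compartment is
assigned its conductivity at one representative frequency, 1 kHz, chosen
because (i) device-reported static impedance tracks the 1 kHz impedance of
the electrode–body system, and (ii) at ECT intensities tissue impedance is
approximately frequency-invariant across the waveform's main spectral lobe
(~10 Hz–4 kHz), which contains 1 kHz. Permittivity and any time dependence
of the adaptation are neglected throughout.

The single nonlinearity is the superficial scalp. Its conductivity is an
instantaneous, piecewise-linear function of the local electric-field
magnitude E:

    sigma_SS(E) = A            0 <= E < B
                = C·E − D      B <= E < E_sat
                = sigma_ss_max E >= E_sat,   E_sat = (sigma_ss_max + D)/C

with subject-invariant constants A = 5·10⁻³ S/m, B = 85 V/m,
C = 4.49·10⁻⁴ S·m⁻¹/(V·m⁻¹), D = 0.032 S/m, and a subject-specific
saturation conductivity `sigma_ss_max`. As printed, the function has a
small upward jump at E = B (A = 0.005 vs C·B − D ≈ 0.006165 S/m); we
implement it verbatim. An optional linear blend of width `blend_width`
across the threshold exists for solver robustness experiments and defaults
to off. Two subject parameters complete the model: `sigma_ss_max` and the
fixed deep-scalp conductivity `sigma_DS` (soft bounds 4.5·10⁻⁴–8·10⁻³ S/m).
When `sigma_ss_max` is set at or below C·B − D the knee cannot exist;
`ScalpParams` then degenerates the knee to B, which makes the function flat
when `sigma_ss_max` equals the floor — the "no adaptivity" limit used in
tests. The standalone `saturation_field()` helper instead raises in that
regime, since the quantity it names is undefined.

Fixed tissue conductivities (S/m): skull 0.01, gray matter 0.276, white
matter 0.126, CSF/meninges 0.85, electrode gel 0.018, air 10⁻¹⁵.

## Waveform analysis

The stimulus is an alternating-polarity rectangular train: +A on [0, Δ),
−A on [T/2, T/2 + Δ), zero elsewhere, repeating with period T. A device
"20 Hz" dose setting is interpreted as the full-cycle rate (T = 50 ms, one
positive plus one negative pulse per cycle), matching the single-period
definition above; device documentation sometimes quotes pulses per second,
which would halve T. The two-sided coefficient magnitudes are
|C_n| = (A/πn)·|sin(πnΔ/T)|·(1 − (−1)ⁿ); the single-sided FFT amplitude of
a sampled record equals 2|C_n| at n/T. Sampling uses half-open intervals,
so a sample landing exactly on a falling edge takes the post-edge value;
when the sample rate divides the period the edge arithmetic is done in
integer sample counts to avoid floating-point misclassification. No window
is applied; spectral comparisons use records cut to an integer number of
periods. The static test signal is idealized as an 800 Hz ±2 µA square
wave (Δ = T/2).

## Circuit fitting

`fit_rrc` minimizes the unweighted sum of squared real- and imaginary-part
residuals (absolute ohms) over points with frequency strictly above the
floor (default 100 Hz, where measured spectra depart from any R-RC
circuit). Parameters are optimized in log space with Levenberg–Marquardt,
making positivity structural and the search unconstrained. Initialization
is deterministic: Rs₀ from the highest-frequency real part, Rp₀ from the
lowest retained real part minus Rs₀, Cp₀ from the relaxation condition
2πf*·Rp₀Cp₀ = 1 at the most negative imaginary part. No random restarts;
identical inputs give identical fits. 1 kHz magnitudes are rounded half
away from zero when reported in integer ohms.

## Phantoms

Subject MRI meshes are out of scope; the solver runs on synthetic phantoms.

The default is a layered slab, 14 × 6.3 cm in plane: superficial scalp
3.5 mm, deep scalp 3.5 mm (a 7 mm scalp bisected into the two layers),
skull 7 mm, CSF 3 mm, gray and white matter 10 mm each, with two
4.2 × 4.9 cm electrode pads (1.7 mm gel, σ = 0.018 S/m) side by side on the
top face — a flattened caricature of a bifrontal montage on the forehead.
It isolates the series scalp/skull path that the adaptive mechanism
parameterizes and admits an exact series-resistance oracle when driven with
full-face electrodes (`build_column`). Layer thicknesses are declared
defaults, not inferred anatomy. Meshing is structured-hexahedral:
1.5 mm through-thickness resolution (every layer ≥ 2 elements) and 7 mm
in-plane resolution, chosen so that a full calibration stays cheap; halving
both resolutions moves the uniform-conductivity slab impedance by ~1.2%
(patch-edge fringing dominates the residual discretization error). Air is
not meshed in the slab — at 10⁻¹⁵ S/m it carries nothing.

A concentric-shells phantom (voxelized spheres, reduced scale) probes
curvature effects. At shell voxel sizes the 1.7 mm gel layer cannot be
voxelized reliably (the band is thinner than a voxel and staircase gaps
would disconnect the caps), so shell electrodes are idealized as polar
surface caps directly on the superficial scalp.

Meshes are exchanged as legacy-ASCII VTK unstructured grids (hexahedra,
integer `tissue_id` cell data) with a JSON sidecar carrying the id→label
map and the two terminal face sets.

## FEM and the adaptive loop

First-order trilinear hexahedra, element-constant conductivity and field
(field = magnitude of the negative potential gradient at the element
center). The driven electrode injects the total current as a uniform
current density over its outer gel faces; the ground electrode's outer
faces are held at V = 0. Terminal impedance is the area-weighted mean
driven-face potential divided by the applied current. A complete-electrode
(contact-impedance) model is deliberately omitted: interface effects are
attributed to the superficial-scalp properties the transfer function
already represents. Linear systems are solved with Jacobi-preconditioned
conjugate gradients (relative tolerance 10⁻³ by default; oracle-grade tests
tighten it), assembled in double precision so a 14-decade conductivity
range (air) stays tolerable. A sparse direct solver is available via
`SolverSettings(linear_solver="direct")`.

The field–conductivity fixed point is solved by under-relaxed Picard
iteration rather than Newton: the transfer function's jump at B leaves
Newton's derivative undefined, while Picard with ω = 0.5 is robust against
threshold chatter. Each step solves the linear problem, evaluates
sigma_SS on the superficial-scalp element fields, and relaxes
σ ← (1−ω)σ + ω·sigma_SS(E), warm-starting CG from the previous potentials.
Convergence requires both the relative impedance change and the maximum
relative conductivity change to fall below the adaptive tolerance
(default 10⁻³); hitting the iteration cap returns `converged=False` with
the full per-iteration trace rather than raising. On the default slab the
dynamic (900 mA) solve converges in ~15–25 iterations at 10⁻³–10⁻⁶
tolerances; the static (2 µA) solve converges immediately because scalp
fields (~0.2 V/m) never reach the threshold.

## Calibration

Given a subject's (static, dynamic) impedance pair, `calibrate` exploits
two monotonicities verified on the default phantom: static impedance is
strictly decreasing in sigma_DS (and essentially independent of
sigma_ss_max, since 2 µA never activates the transfer function), and
dynamic impedance is strictly decreasing in sigma_ss_max at fixed sigma_DS.
Nested bisection on the log-parameters therefore suffices and is fully
deterministic: sigma_DS is bracketed on the static residual, then
sigma_ss_max on the dynamic residual; a second round runs only if
cross-sensitivity leaves a residual above the match tolerance (2% relative
per impedance, the declared meaning of "matched"). Forward solves inside
calibration use tightened tolerances (linear 10⁻⁹, adaptive 10⁻⁶) because
the bisection must resolve impedance differences well below 2%. Missing
brackets raise an error naming the limiting bound; exhausting the
evaluation budget returns `converged=False` with best-so-far values. The
static model current defaults to the 2 µA device test amplitude and can be
overridden (e.g., 1 mA) for intensity-comparison studies.

## What the phantom results do and do not show

The slab reproduces the mechanisms — static ≫ dynamic impedance, field
saturation of scalp conductivity around electrodes, monotone impedance vs
intensity, and recoverability of (sigma_DS, sigma_ss_max) from an impedance
pair (a 3×3 grid spanning the subject ranges recovers both parameters
within 5%). It does not reproduce subject-specific magnitudes: clinical
impedances and brain-field values depend on individual anatomy (current
spreading over the whole scalp, skull thickness variation, CSF geometry)
that a slab or shell cannot represent. Calibrated parameters on a phantom
are therefore internally consistent but not comparable to values fitted on
MRI-derived meshes.

## Numerical choices and limitations

* Problem sizes: default slab ≈ 5,000 elements; test columns ≤ a few
  hundred; shells ≈ 7,000–34,000. These keep a full calibration at ~30
  forward solves in tens of seconds.
* Ties/degeneracies: frequency floor is exclusive (points at exactly
  100 Hz are dropped); f = 0 circuit impedance returns Rs + Rp exactly;
  element conductivities are floored at 10⁻¹⁵ S/m.
* The R-RC model is not valid below ~100 Hz and no constant-phase or
  multi-dispersion elements are provided.
* The adaptive loop is a fixed-point method; with the verbatim jump at B a
  small set of elements can in principle oscillate across the threshold.
  Under-relaxation damps this in practice; persistent cases surface as
  `converged=False`, and the optional blend width exists for such studies.
* No randomness anywhere in the solver or calibration; all stochastic
  tests (noisy-fit recovery) fix their generator seeds.
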
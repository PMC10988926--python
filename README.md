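# ectsim

Quasi-static, representative-frequency modeling of electroconvulsive
therapy (ECT), for researchers studying the biophysics of transcranial
electrical stimulation at ECT intensities.

ECT devices report two impedances for the same electrode montage: a
*static* impedance, probed before treatment with a tiny test current
(~2 µA, ~800 Hz), and a much lower *dynamic* impedance during the 800–900 mA
stimulus itself. The gap is dominated by the skin: at high local electric
fields, superficial scalp conductivity rises by up to two orders of
magnitude. `ectsim` implements a modeling pipeline that reconciles this
with the quasi-static (Laplace) treatment of tissue current flow by
assigning every compartment its conductivity at one representative
frequency, 1 kHz, and letting only the superficial scalp adapt to the local
field.

## What it computes

**Waveforms.** The ECT stimulus is an alternating-polarity rectangular
pulse train: amplitude A, pulse width Δ, full cycle T. Its two-sided
Fourier coefficient magnitudes are

```
|C_n| = (A / πn) · |sin(πnΔ/T)| · (1 − (−1)^n)
```

so even harmonics vanish and the spectral envelope has its first null at
1/Δ. `ectsim.waveforms` generates sampled trains and computes analytic and
FFT amplitude spectra.

**Lumped impedance.** Low-current electrode–body impedance above ~100 Hz is
captured by an R-RC circuit, Z(f) = Rs + Rp / (1 + j·2πf·RpCp).
`ectsim.circuits` evaluates, fits (deterministic Levenberg–Marquardt on
log-parameters, points >100 Hz only), and reports the 1 kHz magnitude that
device static-impedance readings approximate.

**Adaptive conductivity.** Superficial-scalp conductivity follows a
piecewise-linear transfer function of local field magnitude E:
σ_SS = A₀ below a threshold B, C·E − D up to a subject-specific saturation
σ̄_SS, reached at E_sat = (σ̄_SS + D)/C (defaults A₀ = 5·10⁻³ S/m, B = 85 V/m,
C = 4.49·10⁻⁴, D = 0.032).

**FEM.** `ectsim.phantom` builds synthetic multilayer head phantoms
(layered slab with two 4.2 × 4.9 cm gel pad electrodes, or concentric
shells); `ectsim.fem` solves ∇·(σ∇V) = 0 with trilinear hexahedra and runs
the under-relaxed Picard loop that makes scalp conductivity and field
mutually consistent. `ectsim.calibrate` inverts the model: given a
subject's (static, dynamic) impedance pair it finds the deep-scalp
conductivity σ_DS and saturation conductivity σ̄_SS by nested bisection.

## Worked example

```python
import ectsim as es

# 1. device waveform: 900 mA, 0.5 ms pulses, 20 Hz alternating cycles
spec = es.PulseTrainSpec(amplitude=0.9, pulse_width=0.5e-3, period=50e-3,
                         duration=1.0, sample_rate=200e3)
print(es.analytic_harmonics(spec, 1).coefficient_magnitude[0])  # |C1|
print(es.first_envelope_null(spec))

# 2. a subject's fitted R-RC circuit and its 1 kHz impedance
circuit = es.RRCCircuit(series_resistance=522, parallel_resistance=9.89e3,
                        parallel_capacitance=175e-9)
print(es.round_to_ohm(es.magnitude_at_1khz(circuit)))

# 3. adaptive FEM on the default slab phantom
mesh = es.build_phantom(es.default_slab_spec())
scalp = es.ScalpParams(deep_scalp_conductivity=2e-3,
                       max_superficial_conductivity=0.25)
tissues = es.TissueTable()
static = es.solve_adaptive(mesh, tissues, scalp,
                           bc=es.BoundaryCondition(es.STATIC_CURRENT))
dynamic = es.solve_adaptive(mesh, tissues, scalp,
                            bc=es.BoundaryCondition(es.DYNAMIC_CURRENT))

# 4. recover the scalp parameters from the impedance pair alone
target = es.ClinicalImpedancePair(static.impedance, dynamic.impedance)
fit = es.calibrate(mesh, tissues, es.TransferFunctionParams(), target)
```

prints

```
fundamental |C1| = 0.018 A at 20.0 Hz
first envelope null = 2000.0 Hz
1 kHz impedance = 1086 ohm
static impedance  = 2225 ohm (2 iterations)
dynamic impedance = 646 ohm (13 iterations)
calibrated sigma_DS = 0.00200 S/m, sigma_SS_max = 0.2496 S/m (30 forward solves)
```

The 0.018 A fundamental sits at the 20 Hz cycle rate and the spectrum's
main lobe ends at 1/Δ = 2 kHz, bracketing the 1 kHz representative
frequency. The subject circuit's 1 kHz magnitude (1086 Ω) is what the
device's static reading approximates. On the phantom, the 2 µA solve
leaves scalp fields far below the 85 V/m threshold (impedance 2225 Ω,
converged immediately), while at 900 mA the superficial scalp saturates and
impedance drops to 646 Ω. Calibration then recovers the scalp parameters
that generated the pair to a fraction of a percent.

A `ectsim` console script exposes the same steps
(`spectrum`, `fit-circuit`, `phantom`, `solve`, `calibrate`); see
`ectsim --help`.

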
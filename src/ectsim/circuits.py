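"""R-RC lumped model of low-current electrode-body impedance.

A series resistance Rs in series with a parallel resistor-capacitor pair
(Rp, Cp) is the minimal circuit reproducing the measured impedance spectrum
of adhesive ECT electrodes above ~100 Hz:

    Z(f) = Rs + Rp / (1 + j 2 pi f Rp Cp)

At DC the capacitor is open (Z = Rs + Rp, purely real); at high frequency it
shorts Rp (Z -> Rs).  In the complex plane the model traces the semicircle
(Re - Rs - Rp/2)^2 + Im^2 = (Rp/2)^2.  Below ~100 Hz measured spectra rise
nonlinearly in both components and depart from this circuit, so fitting
retains only data above a frequency floor (default 100 Hz, exclusive).  The
1 kHz impedance magnitude of the fitted circuit is the quantity an ECT
device's "static impedance" approximates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RRCCircuit",
    "ImpedanceSpectrum",
    "CircuitFitResult",
    "CircuitFitError",
    "circuit_impedance",
    "magnitude_at_1khz",
    "round_to_ohm",
    "fit_rrc",
    "synthesize_spectrum",
    "load_spectrum",
    "save_spectrum",
]

SPECTRUM_COLUMNS = ("frequency_hz", "z_real_ohm", "z_imag_ohm")


@dataclass(frozen=True)
class RRCCircuit:
    """Rs + (Rp || Cp) circuit; resistances in ohms, capacitance in farads."""

    series_resistance: float
    parallel_resistance: float
    parallel_capacitance: float

    def __post_init__(self) -> None:
        for name in (
            "series_resistance",
            "parallel_resistance",
            "parallel_capacitance",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Measured complex impedance vs frequency (ohms vs Hz)."""

    frequency: np.ndarray
    impedance: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        z = np.asarray(self.impedance, dtype=complex)
        if f.shape != z.shape:
            raise ValueError("frequency and impedance must have equal length")
        if not np.all(f > 0):
            raise ValueError("frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        if not np.all(z.real > 0):
            raise ValueError("real parts must be positive")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "impedance", z)


@dataclass(frozen=True)
class CircuitFitResult:
    circuit: RRCCircuit
    residual_norm: float
    n_points_used: int
    frequency_floor: float


class CircuitFitError(RuntimeError):
    """Raised when the optimizer fails; carries best-so-far parameters."""

    def __init__(self, message: str, best: RRCCircuit | None = None):
        super().__init__(message)
        self.best = best


def circuit_impedance(circuit: RRCCircuit, frequency) -> complex | np.ndarray:
    """Z(f) = Rs + Rp / (1 + j 2 pi f Rp Cp); f = 0 gives Rs + Rp exactly."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    tau = circuit.parallel_resistance * circuit.parallel_capacitance
    z = circuit.series_resistance + circuit.parallel_resistance / (
        1.0 + 1j * 2.0 * np.pi * f * tau
    )
    return complex(z) if np.isscalar(frequency) else z


def magnitude_at_1khz(circuit: RRCCircuit) -> float:
    """|Z| of the circuit at 1 kHz, in ohms."""
    return abs(circuit_impedance(circuit, 1000.0))


def round_to_ohm(value: float) -> int:
    """Round half away from zero to integer ohms."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def synthesize_spectrum(circuit: RRCCircuit, frequency) -> ImpedanceSpectrum:
    """Exact model spectrum on a frequency grid (for tests and round trips)."""
    f = np.asarray(frequency, dtype=float)
    return ImpedanceSpectrum(frequency=f, impedance=circuit_impedance(circuit, f))


def _initial_guess(f: np.ndarray, z: np.ndarray) -> RRCCircuit:
    # Rs from the high-frequency real limit, Rp from the low-frequency one,
    # Cp from the relaxation peak 2 pi f* Rp Cp = 1 at the most negative Im.
    rs0 = max(float(z.real[-1]), 1e-3)
    rp0 = max(float(z.real[0]) - rs0, 1e-3)
    f_star = float(f[np.argmin(z.imag)])
    cp0 = 1.0 / (2.0 * np.pi * f_star * rp0)
    return RRCCircuit(rs0, rp0, cp0)


def fit_rrc(
    spectrum: ImpedanceSpectrum,
    frequency_floor: float = 100.0,
    max_iterations: int = 2000,
) -> CircuitFitResult:
    """Fit (Rs, Rp, Cp) to a spectrum by Levenberg-Marquardt least squares.

    Only points with frequency strictly above ``frequency_floor`` are used.
    The residual stacks real- and imaginary-part errors in absolute ohms.
    Parameters are searched in log space (strictly positive by construction)
    from a deterministic initialization, so identical inputs always give
    identical fits.
    """
    keep = spectrum.frequency > frequency_floor
    f = spectrum.frequency[keep]
    z = spectrum.impedance[keep]
    if len(f) < 3:
        raise ValueError(
            f"need at least 3 points above {frequency_floor} Hz, got {len(f)}"
        )
    guess = _initial_guess(f, z)
    x0 = np.log(
        [
            guess.series_resistance,
            guess.parallel_resistance,
            guess.parallel_capacitance,
        ]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        rs, rp, cp = np.exp(x)
        zm = rs + rp / (1.0 + 1j * 2.0 * np.pi * f * rp * cp)
        return np.concatenate([(zm.real - z.real), (zm.imag - z.imag)])

    sol = least_squares(residuals, x0, method="lm", max_nfev=max_iterations)
    rs, rp, cp = np.exp(sol.x)
    circuit = RRCCircuit(float(rs), float(rp), float(cp))
    if not sol.success:
        raise CircuitFitError(
            f"R-RC fit did not converge: {sol.message}", best=circuit
        )
    return CircuitFitResult(
        circuit=circuit,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_points_used=int(len(f)),
        frequency_floor=float(frequency_floor),
    )


def load_spectrum(path: str | Path) -> ImpedanceSpectrum:
    """Read `frequency_hz,z_real_ohm,z_imag_ohm` CSV; rows sorted on load."""
    df = pd.read_csv(path)
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    numeric = df[list(SPECTRUM_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        lines = ", ".join(str(i + 2) for i in numeric.index[bad])
        raise ValueError(f"{path}: malformed row(s) at line(s) {lines}")
    numeric = numeric.sort_values("frequency_hz")
    return ImpedanceSpectrum(
        frequency=numeric["frequency_hz"].to_numpy(),
        impedance=numeric["z_real_ohm"].to_numpy()
        + 1j * numeric["z_imag_ohm"].to_numpy(),
    )


def save_spectrum(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": spectrum.frequency,
            "z_real_ohm": spectrum.impedance.real,
            "z_imag_ohm": spectrum.impedance.imag,
        }
    ).to_csv(path, index=False)
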
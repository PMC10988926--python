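"""Idealized ECT device waveforms and their amplitude spectra.

ECT devices deliver trains of rectangular, constant-current pulses with
alternating polarity.  One full period ``T`` contains a positive pulse of
width ``Delta`` followed, half a period later, by its negative mirror:

    x(t) = +A   for 0     <= t < Delta
    x(t) = -A   for T/2   <= t < T/2 + Delta
    x(t) = 0    otherwise

The two-sided Fourier coefficient magnitudes of this train are

    |C_n| = (A / (pi n)) * |sin(pi n Delta / T)| * (1 - (-1)^n)

so all even harmonics vanish and the ``sin`` envelope has its first null at
frequency ``1/Delta``.  The single-sided amplitude spectrum measured from an
FFT of the sampled train equals ``2 |C_n|`` at each harmonic ``n/T``.

The low-intensity "static impedance" test signal of the Thymatron device is
modeled as an 800 Hz, +/-2 uA square wave (the ``Delta = T/2`` limit of the
same train).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseTrainSpec",
    "SampledSignal",
    "HarmonicSpectrum",
    "NumericSpectrum",
    "generate_pulse_train",
    "analytic_harmonics",
    "numeric_spectrum",
    "first_envelope_null",
    "static_test_spec",
]


@dataclass(frozen=True)
class PulseTrainSpec:
    """Alternating-polarity rectangular pulse train.

    Parameters
    ----------
    amplitude : float
        Peak current in amperes (symbol ``A``), > 0.
    pulse_width : float
        Width of each rectangular pulse in seconds (symbol ``Delta``).
    period : float
        One full alternating cycle in seconds (symbol ``T``): a positive
        pulse followed by a negative pulse.  A device "20 Hz" dose setting
        is read as this full-cycle rate, i.e. T = 50 ms.
    duration : float
        Record length in seconds.
    sample_rate : float
        Sampling frequency in Hz; must resolve the pulse edges
        (``sample_rate >= 20 / pulse_width``).
    """

    amplitude: float
    pulse_width: float
    period: float
    duration: float
    sample_rate: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not 0 < self.pulse_width <= self.period / 2:
            raise ValueError("pulse_width must satisfy 0 < pulse_width <= period/2")
        if not self.sample_rate >= 20 / self.pulse_width:
            raise ValueError(
                "sample_rate must be >= 20/pulse_width to resolve pulse edges"
            )
        if not self.duration >= self.period:
            raise ValueError("duration must cover at least one period")


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled current signal (times in s, values in A)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Analytic two-sided Fourier coefficient magnitudes |C_n| at n/T."""

    harmonic_index: np.ndarray
    frequency: np.ndarray
    coefficient_magnitude: np.ndarray


@dataclass(frozen=True)
class NumericSpectrum:
    """Single-sided FFT amplitude spectrum (a pure sinusoid of peak a -> a)."""

    frequency: np.ndarray
    amplitude: np.ndarray


def generate_pulse_train(spec: PulseTrainSpec) -> SampledSignal:
    """Sample the alternating-polarity train over its full duration.

    Pulse edges use half-open intervals ``[start, start + Delta)``: a sample
    falling exactly on a falling edge takes the post-edge value.
    """
    n = int(round(spec.duration * spec.sample_rate))
    times = np.arange(n) / spec.sample_rate
    per = spec.period * spec.sample_rate
    if abs(per - round(per)) < 1e-6:
        # integer samples per period: exact edge placement in sample counts
        def snap(x):
            return round(x) if abs(x - round(x)) < 1e-6 else x

        s = np.arange(n) % round(per)
        pw = snap(spec.pulse_width * spec.sample_rate)
        neg0 = snap(spec.period / 2 * spec.sample_rate)
        neg1 = snap((spec.period / 2 + spec.pulse_width) * spec.sample_rate)
        pos = s < pw
        neg = (s >= neg0) & (s < neg1)
    else:
        phase = np.mod(times, spec.period)
        pos = phase < spec.pulse_width
        neg = (phase >= spec.period / 2) & (
            phase < spec.period / 2 + spec.pulse_width
        )
    values = np.zeros(n)
    values[pos] = spec.amplitude
    values[neg] = -spec.amplitude
    return SampledSignal(times=times, values=values)


def analytic_harmonics(spec: PulseTrainSpec, n_max: int) -> HarmonicSpectrum:
    """Closed-form |C_n| for n = 1..n_max.

    |C_n| = (A/(pi n)) * |sin(pi n Delta/T)| * (1 - (-1)^n); every even
    harmonic is extinguished by the alternating polarity.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n = np.arange(1, n_max + 1)
    envelope = np.sin(np.pi * n * spec.pulse_width / spec.period)
    parity = 1 - (-1.0) ** n
    mag = np.abs(spec.amplitude / (np.pi * n) * envelope * parity)
    return HarmonicSpectrum(
        harmonic_index=n,
        frequency=n / spec.period,
        coefficient_magnitude=mag,
    )


def numeric_spectrum(signal: SampledSignal, rtol: float = 1e-9) -> NumericSpectrum:
    """Single-sided amplitude spectrum of a uniformly sampled record.

    Normalized so a pure sinusoid of peak amplitude ``a`` yields ``a`` at its
    frequency bin; frequency resolution is 1/duration.  No window is applied,
    so callers comparing against harmonic lines should use records that span
    an integer number of periods.
    """
    n = len(signal.values)
    if n < 2:
        raise ValueError("signal must contain at least 2 samples")
    dt = np.diff(signal.times)
    if not np.allclose(dt, dt[0], rtol=rtol, atol=rtol * abs(dt[0])):
        raise ValueError("signal must be uniformly sampled")
    amp = np.abs(np.fft.rfft(signal.values)) / n
    # double all bins except DC (and Nyquist for even-length records)
    if n % 2 == 0:
        amp[1:-1] *= 2.0
    else:
        amp[1:] *= 2.0
    freq = np.fft.rfftfreq(n, d=float(dt[0]))
    return NumericSpectrum(frequency=freq, amplitude=amp)


def first_envelope_null(spec: PulseTrainSpec) -> float:
    """First zero of the sin(pi f Delta) spectral envelope, = 1/Delta in Hz.

    For a 0.5 ms pulse width the main lobe of frequency content therefore
    ends at 2 kHz, and at 4 kHz for 0.25 ms.
    """
    return 1.0 / spec.pulse_width


def static_test_spec(
    amplitude: float = 2e-6, frequency: float = 800.0, duration: float = 0.1
) -> PulseTrainSpec:
    """Idealized device static-impedance test signal: an 800 Hz square wave
    of +/-2 uA peak, i.e. the Delta = T/2 limit of the pulse train."""
    period = 1.0 / frequency
    return PulseTrainSpec(
        amplitude=amplitude,
        pulse_width=period / 2,
        period=period,
        duration=duration,
        sample_rate=max(40 / period, 100 * frequency),
    )
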
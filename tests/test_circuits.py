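"""R-RC circuit evaluation, fitting, and spectrum I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ectsim import (
    ImpedanceSpectrum,
    RRCCircuit,
    circuit_impedance,
    fit_rrc,
    load_spectrum,
    magnitude_at_1khz,
    round_to_ohm,
    save_spectrum,
    synthesize_spectrum,
)

# subject-fitted circuits: (Rs ohm, Rp ohm, Cp F, printed 1 kHz magnitude)
SUBJECT_CIRCUITS = {
    201: (522, 9.89e3, 175e-9, 1086),
    202: (681, 13.17e3, 138e-9, 1386),
    203: (506, 5.52e3, 210e-9, 960),
    204: (508, 13.44e3, 138e-9, 1297),
    205: (555, 22.59e3, 119e-9, 1475),
    206: (449, 4.24e3, 219e-9, 906),
    208: (557, 6.70e3, 160e-9, 1203),
    209: (432, 2.57e3, 263e-9, 806),
    210: (374, 3.97e3, 277e-9, 723),
}

circuit_strategy = st.builds(
    RRCCircuit,
    st.floats(1.0, 1e4),
    st.floats(10.0, 1e5),
    st.floats(1e-9, 1e-6),
)


class TestCircuitImpedance:
    def test_dc_limit_is_purely_real_sum(self):
        c = RRCCircuit(500.0, 10e3, 150e-9)
        z = circuit_impedance(c, 0.0)
        assert z == pytest.approx(10.5e3)
        assert z.imag == 0.0

    def test_high_frequency_limit_is_rs(self):
        c = RRCCircuit(500.0, 10e3, 150e-9)
        assert abs(circuit_impedance(c, 1e9)) == pytest.approx(500.0, rel=1e-3)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            circuit_impedance(RRCCircuit(1, 1, 1e-9), -1.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError, match="parallel_capacitance"):
            RRCCircuit(1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "subject, params", SUBJECT_CIRCUITS.items(), ids=str
    )
    def test_subject_circuits_reproduce_printed_1khz(self, subject, params):
        rs, rp, cp, printed = params
        z = magnitude_at_1khz(RRCCircuit(rs, rp, cp))
        assert abs(round_to_ohm(z) - printed) <= 0.01 * printed

    def test_vanishing_capacitance_limit(self):
        # Cp -> 0: frequency independent, Rs + Rp at any frequency
        c = RRCCircuit(432.0, 2.57e3, 1e-18)
        assert magnitude_at_1khz(c) == pytest.approx(432.0 + 2.57e3, rel=1e-9)

    @given(circuit_strategy)
    def test_magnitude_non_increasing_in_frequency(self, circuit):
        f = np.logspace(0, 5, 200)
        mag = np.abs(circuit_impedance(circuit, f))
        assert np.all(np.diff(mag) <= 1e-9 * mag[:-1])

    @given(circuit_strategy)
    def test_complex_locus_traces_semicircular_arc(self, circuit):
        """(Re - Rs - Rp/2)^2 + Im^2 = (Rp/2)^2 on a dense grid."""
        f = np.logspace(0, 6, 100)
        z = circuit_impedance(circuit, f)
        rs, rp = circuit.series_resistance, circuit.parallel_resistance
        radius_sq = (z.real - rs - rp / 2) ** 2 + z.imag**2
        assert np.allclose(radius_sq, (rp / 2) ** 2, rtol=1e-9)


class TestFitRRC:
    truth = RRCCircuit(500.0, 10e3, 150e-9)
    freqs = np.logspace(2, 3, 20)  # 100 Hz .. 1 kHz

    def _relerr(self, fitted):
        t, f = self.truth, fitted
        return max(
            abs(f.series_resistance / t.series_resistance - 1),
            abs(f.parallel_resistance / t.parallel_resistance - 1),
            abs(f.parallel_capacitance / t.parallel_capacitance - 1),
        )

    def test_exact_recovery_from_noiseless_spectrum(self):
        spec = synthesize_spectrum(self.truth, self.freqs)
        fit = fit_rrc(spec)
        assert self._relerr(fit.circuit) < 1e-3
        assert fit.n_points_used == np.sum(self.freqs > 100.0)

    def test_recovery_under_one_percent_noise(self):
        rng = np.random.default_rng(20230316)
        z = circuit_impedance(self.truth, self.freqs)
        noisy = z.real * (1 + 0.01 * rng.standard_normal(len(z))) + 1j * (
            z.imag * (1 + 0.01 * rng.standard_normal(len(z)))
        )
        fit = fit_rrc(ImpedanceSpectrum(self.freqs, noisy))
        assert self._relerr(fit.circuit) < 0.05

    def test_points_below_floor_are_ignored(self):
        f_lo = np.array([10.0, 30.0, 60.0, 90.0])
        spec_hi = synthesize_spectrum(self.truth, self.freqs)
        with_lo = ImpedanceSpectrum(
            np.concatenate([f_lo, self.freqs]),
            np.concatenate(
                [circuit_impedance(self.truth, f_lo) * 3.0, spec_hi.impedance]
            ),
        )
        fit_a = fit_rrc(spec_hi)
        fit_b = fit_rrc(with_lo)
        assert fit_a.circuit == fit_b.circuit

    def test_fit_is_idempotent(self):
        fit1 = fit_rrc(synthesize_spectrum(self.truth, self.freqs))
        fit2 = fit_rrc(synthesize_spectrum(fit1.circuit, self.freqs))
        assert self._relerr(fit2.circuit) < 1e-3

    def test_too_few_points_rejected(self):
        spec = synthesize_spectrum(self.truth, np.array([150.0, 300.0]))
        with pytest.raises(ValueError, match="at least 3"):
            fit_rrc(spec)


class TestSpectrumIO:
    def test_round_trip(self, tmp_path):
        spec = synthesize_spectrum(RRCCircuit(400, 5e3, 2e-7), np.array([120.0, 400.0, 900.0]))
        path = tmp_path / "spec.csv"
        save_spectrum(spec, path)
        back = load_spectrum(path)
        assert np.allclose(back.frequency, spec.frequency)
        assert np.allclose(back.impedance, spec.impedance)

    def test_unsorted_rows_sorted_on_load(self, tmp_path):
        path = tmp_path / "spec.csv"
        path.write_text(
            "frequency_hz,z_real_ohm,z_imag_ohm\n"
            "900,450,-100\n120,5000,-900\n400,1200,-1500\n"
        )
        spec = load_spectrum(path)
        assert list(spec.frequency) == [120.0, 400.0, 900.0]
        assert spec.impedance[0] == 5000 - 900j

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "spec.csv"
        path.write_text("frequency_hz,z_real_ohm\n100,5\n")
        with pytest.raises(ValueError, match="z_imag_ohm"):
            load_spectrum(path)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "spec.csv"
        path.write_text(
            "frequency_hz,z_real_ohm,z_imag_ohm\n100,5,-1\n200,oops,-2\n"
        )
        with pytest.raises(ValueError, match="line.*3"):
            load_spectrum(path)
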
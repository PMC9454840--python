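import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wellfield import (
    InvalidWaveformError,
    PulseWaveform,
    adiabatic_temp_rise,
    average_power,
    deposited_energy,
    dose_table,
    duty_cycle,
    sample_waveform,
    standard_settings,
)

WF_20HZ = PulseWaveform(1.0, 20.0, 3.6e-3)
WF_79HZ = PulseWaveform(5.0, 7.9, 10e-3)


class TestWaveform:
    def test_invalid_waveforms_rejected(self):
        with pytest.raises(InvalidWaveformError):
            PulseWaveform(1.0, 20.0, 0.06)  # tau > 1/f
        with pytest.raises(InvalidWaveformError):
            PulseWaveform(-1.0, 20.0, 3.6e-3)
        with pytest.raises(InvalidWaveformError):
            PulseWaveform(1.0, 20.0, 0.0)

    @pytest.mark.parametrize(
        "wf,expected",
        [(WF_20HZ, 0.072), (WF_79HZ, 0.079)],
    )
    def test_duty_cycle_of_stimulator_settings(self, wf, expected):
        assert duty_cycle(wf) == pytest.approx(expected)

    def test_continuous_stimulation_duty_one(self):
        wf = PulseWaveform(1.0, 20.0, 1 / 20.0)
        assert duty_cycle(wf) == pytest.approx(1.0)


class TestSampling:
    def test_symmetric_biphasic(self):
        _, v = sample_waveform(WF_20HZ, 100e3, 1)
        assert v.max() == 1.0
        assert v.min() == -1.0
        assert abs(v.mean()) < 1e-9

    def test_nonzero_fraction_matches_duty(self):
        _, v = sample_waveform(WF_79HZ, 100e3, 10)
        assert np.mean(v != 0) == pytest.approx(0.079, abs=2e-4)

    def test_zero_amplitude(self):
        wf = PulseWaveform(0.0, 20.0, 3.6e-3)
        _, v = sample_waveform(wf, 100e3, 2)
        assert np.all(v == 0)

    def test_sample_rate_floor(self):
        with pytest.raises(InvalidWaveformError):
            sample_waveform(WF_20HZ, 2000.0, 1)  # < 10 samples per pulse

    def test_time_axis_uniform(self):
        t, v = sample_waveform(WF_20HZ, 50e3, 3)
        assert len(t) == len(v)
        np.testing.assert_allclose(np.diff(t), 1 / 50e3, rtol=1e-9)


class TestPowerAndEnergy:
    def test_average_power_closed_form(self):
        # 5 V x 38.5 mA x 7.9% duty
        assert average_power(WF_79HZ, 0.0385) == pytest.approx(
            0.0152, abs=1e-4
        )

    def test_closed_form_matches_numerical_integration(self):
        """V*I*duty equals the time integral of the sampled power trace."""
        for wf, peak in [(WF_79HZ, 0.0385), (WF_20HZ, 0.012)]:
            t, v = sample_waveform(wf, 100e3, 10)
            current = v / wf.amplitude * peak
            numeric = np.trapezoid(v * current, t) / t[-1]
            closed = average_power(wf, peak)
            assert closed == pytest.approx(numeric, rel=5e-3)

    def test_zero_current(self):
        assert average_power(WF_20HZ, 0.0) == 0.0

    def test_continuous_unit_power(self):
        wf = PulseWaveform(1.0, 10.0, 0.1)
        assert average_power(wf, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "wf,expected_j",
        [(WF_79HZ, 9.1), (PulseWaveform(5.0, 20.0, 3.6e-3), 8.3)],
    )
    def test_session_energy(self, wf, expected_j):
        assert deposited_energy(wf, 0.0385, 600.0) == pytest.approx(
            expected_j, abs=0.1
        )

    def test_zero_duration(self):
        assert deposited_energy(WF_79HZ, 0.0385, 0.0) == 0.0

    @given(
        t1=st.floats(0, 1000),
        t2=st.floats(0, 1000),
        peak=st.floats(0, 0.1),
    )
    def test_energy_additive_in_duration(self, t1, t2, peak):
        total = deposited_energy(WF_79HZ, peak, t1 + t2)
        parts = deposited_energy(WF_79HZ, peak, t1) + deposited_energy(
            WF_79HZ, peak, t2
        )
        assert total == pytest.approx(parts, rel=1e-12, abs=1e-15)


class TestTemperatureBound:
    def test_arithmetic(self):
        assert adiabatic_temp_rise(9.1, 1e-6) == pytest.approx(2.17, abs=0.01)

    def test_zero_energy(self):
        assert adiabatic_temp_rise(0.0, 1e-6) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adiabatic_temp_rise(1.0, 0.0)
        with pytest.raises(ValueError):
            adiabatic_temp_rise(-1.0, 1e-6)


@pytest.fixture(scope="module")
def summaries(chamber, field_1v):
    return dose_table(
        chamber,
        standard_settings(),
        field_1v,
        measurements={"1 V_20 Hz": 0.012, "bogus code": 0.1},
    )


class TestDoseTable:
    def test_one_row_per_setting(self, summaries):
        assert [s.code for s in summaries] == [
            "1 V_20 Hz", "1 V_7.9 Hz", "5 V_20 Hz", "5 V_7.9 Hz",
        ]

    def test_five_volt_rows_are_five_times_one_volt(self, summaries):
        by_code = {s.code: s for s in summaries}
        for freq in ("20 Hz", "7.9 Hz"):
            low, high = by_code[f"1 V_{freq}"], by_code[f"5 V_{freq}"]
            assert high.field_strength == pytest.approx(
                5 * low.field_strength, rel=1e-12
            )
            assert high.theoretical_current == pytest.approx(
                5 * low.theoretical_current, rel=1e-12
            )

    def test_measurements_merged_and_unknown_codes_ignored(self, summaries):
        by_code = {s.code: s for s in summaries}
        assert by_code["1 V_20 Hz"].measured_current == 0.012
        assert by_code["5 V_20 Hz"].measured_current is None

    def test_energy_consistent_with_power(self, summaries):
        for s in summaries:
            assert s.deposited_energy == pytest.approx(
                s.average_power * s.duration, rel=1e-12
            )
            assert 0 < s.duty_cycle <= 1
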
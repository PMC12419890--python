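"""Force-trace decomposition: steady-state windows, pass arithmetic, corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutmech.errors import (
    InsufficientSteadyStateError,
    InvalidInputError,
    TraceFormatError,
)
from cutmech.trace_processing import (
    NEGATIVE_FRACTURE_FORCE,
    CutMeasurement,
    ForceTrace,
    SteadyStateWindow,
    decompose_passes,
    detect_steady_state,
    read_trace,
    spacing_fraction,
    thickness_correct,
    write_trace,
)

SPEED = 0.3e-3  # m/s


def make_trace(disp_mm, force_mN, pass_id="first"):
    disp = np.asarray(disp_mm) * 1e-3
    return ForceTrace(
        time=disp / SPEED, force=np.asarray(force_mN) * 1e-3,
        stage_speed=SPEED, pass_id=pass_id,
    )


def peak_plateau_trace(peak_mN=40.0, plateau_mN=30.0, peak_at_mm=0.8,
                       travel_mm=5.0, n=1501, noise_sd_mN=0.0, rng=None):
    disp = np.linspace(0.0, travel_mm, n)
    force = np.where(
        disp <= peak_at_mm, peak_mN * disp / peak_at_mm, plateau_mN
    )
    if noise_sd_mN > 0:
        force = force + rng.normal(0.0, noise_sd_mN, n)
    return make_trace(disp, force)


class TestReadTrace:
    def test_unit_conversion_identity(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,force_mN\n0,0\n1,1\n2,2\n")
        tr = read_trace(p)
        assert np.allclose(tr.force, [0.0, 0.001, 0.002])
        assert np.allclose(tr.time, [0, 1, 2])

    def test_displacement_column_takes_precedence(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("displacement_mm,force_mN\n0,1\n1,1\n2,1\n")
        tr = read_trace(p, stage_speed=SPEED)
        assert np.allclose(tr.disp, [0, 1e-3, 2e-3])

    def test_decreasing_time_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,force_mN\n0,0\n2,1\n1,2\n")
        with pytest.raises(TraceFormatError, match="row"):
            read_trace(p)

    def test_missing_force_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,volts\n0,0\n1,1\n")
        with pytest.raises(TraceFormatError, match="force"):
            read_trace(p)

    def test_write_read_round_trip(self, tmp_path, rng):
        tr = ForceTrace(
            time=np.linspace(0, 16.6, 400),
            force=rng.normal(30e-3, 1e-3, 400),
        )
        write_trace(tr, tmp_path / "rt.csv")
        back = read_trace(tmp_path / "rt.csv")
        assert np.allclose(back.time, tr.time, rtol=0, atol=1e-12)
        assert np.allclose(back.force, tr.force, rtol=1e-12, atol=0)


class TestDetectSteadyState:
    def test_noiseless_plateau_recovered_exactly(self):
        w = detect_steady_state(peak_plateau_trace())
        assert w.mean_force * 1e3 == pytest.approx(30.0, abs=1e-12)
        assert w.force_sd == pytest.approx(0.0, abs=1e-12)

    def test_window_spans_configured_length(self):
        w = detect_steady_state(peak_plateau_trace(), window_length=2e-3)
        spacing = 5e-3 / 1500
        assert w.end_displacement - w.start_displacement == pytest.approx(
            2e-3, abs=spacing
        )

    def test_window_starts_after_the_peak(self):
        tr = peak_plateau_trace()
        w = detect_steady_state(tr)
        peak_disp = tr.disp[np.argmax(tr.force)]
        assert w.start_displacement > peak_disp

    def test_constant_trace_mean_is_the_constant(self):
        tr = make_trace(np.linspace(0, 5, 1000), np.full(1000, 12.5))
        w = detect_steady_state(tr)
        assert w.mean_force * 1e3 == pytest.approx(12.5)

    def test_noisy_plateau_mean_within_clt_bound(self, rng):
        truth = 30.0
        tr = peak_plateau_trace(noise_sd_mN=1.0, n=7501, rng=rng)
        w = detect_steady_state(tr)
        n_window = int(2.0 / 5.0 * 7501)
        assert abs(w.mean_force * 1e3 - truth) < 3.0 / np.sqrt(n_window)

    def test_short_steady_state_is_invalid(self):
        # Peak at 4 mm leaves < 2 mm of steady travel: validity rule.
        tr = peak_plateau_trace(peak_at_mm=4.0)
        with pytest.raises(InsufficientSteadyStateError):
            detect_steady_state(tr)

    def test_second_pass_aligned_to_first_window(self):
        first = peak_plateau_trace()
        w1 = detect_steady_state(first)
        second = make_trace(np.linspace(0, 5, 1501), np.full(1501, 4.0), "second")
        w2 = detect_steady_state(second, start_displacement=w1.start_displacement)
        assert w2.start_displacement == pytest.approx(w1.start_displacement, abs=5e-6)
        assert w2.mean_force * 1e3 == pytest.approx(4.0)


class TestDecomposeAndCorrect:
    def test_fracture_force_arithmetic(self):
        m = decompose_passes(
            SteadyStateWindow(1e-3, 3e-3, 33e-3, 0.0),
            SteadyStateWindow(1e-3, 3e-3, 4e-3, 0.0),
        )
        assert m.Ff * 1e3 == pytest.approx(29.0)
        assert spacing_fraction(m) == pytest.approx(4 / 33)
        assert not m.flags

    def test_zero_spacing(self):
        m = decompose_passes(
            SteadyStateWindow(0, 2e-3, 10e-3, 0), SteadyStateWindow(0, 2e-3, 0.0, 0)
        )
        assert m.Ff == m.Fc
        assert spacing_fraction(m) == 0.0

    def test_negative_fracture_force_flagged_not_clipped(self):
        m = decompose_passes(
            SteadyStateWindow(0, 2e-3, 10e-3, 0), SteadyStateWindow(0, 2e-3, 12e-3, 0)
        )
        assert m.Ff * 1e3 == pytest.approx(-2.0)
        assert NEGATIVE_FRACTURE_FORCE in m.flags

    def test_lamina_thickness_correction_hand_oracle(self):
        m = CutMeasurement(Fc=50e-3, Fs=0.0, Ff=50e-3)
        c = thickness_correct(m, 300e-6, 317e-6)
        assert c.Fc * 1e3 == pytest.approx(52.833, rel=1e-4)
        assert c.thickness_corrected

    def test_identity_and_double_correction_guard(self):
        m = CutMeasurement(Fc=50e-3, Fs=5e-3, Ff=45e-3)
        same = thickness_correct(m, 300e-6, 300e-6)
        assert same.Fc == m.Fc
        with pytest.raises(InvalidInputError, match="already"):
            thickness_correct(same, 300e-6, 317e-6)

    def test_spacing_fraction_needs_positive_total(self):
        m = CutMeasurement(Fc=0.0, Fs=0.0, Ff=0.0)
        with pytest.raises(InvalidInputError):
            spacing_fraction(m)

    @given(
        Fc=st.floats(min_value=1e-3, max_value=0.2),
        frac=st.floats(min_value=0.0, max_value=0.5),
        t1=st.floats(min_value=50e-6, max_value=500e-6),
        tref=st.floats(min_value=50e-6, max_value=500e-6),
    )
    @settings(deadline=None, derandomize=True)
    def test_conservation_and_inverse_correction(self, Fc, frac, t1, tref):
        """Fc = Ff + Fs survives correction, and correcting back restores
        the original forces to machine precision."""
        m = CutMeasurement(Fc=Fc, Fs=Fc * frac, Ff=Fc * (1 - frac))
        c = thickness_correct(m, t1, tref)
        assert c.Fc == pytest.approx(c.Ff + c.Fs, rel=1e-12)
        back = thickness_correct(c, tref, t1, force=True)
        assert back.Fc == pytest.approx(m.Fc, rel=1e-12)
        assert back.Fs == pytest.approx(m.Fs, rel=1e-12, abs=1e-18)


def test_trace_invariants_rejected():
    with pytest.raises(InvalidInputError):
        ForceTrace(time=np.array([0.0]), force=np.array([0.0]))
    with pytest.raises(InvalidInputError):
        ForceTrace(time=np.array([0.0, 0.0]), force=np.array([0.0, 1.0]))
    with pytest.raises(InvalidInputError):
        ForceTrace(time=np.array([0.0, 1.0]), force=np.array([0.0, 1.0]),
                   stage_speed=0.0)
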
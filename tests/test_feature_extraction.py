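"""Windowed feature extraction from episode traces."""

import numpy as np
import pytest

from aplysia_hill import feature_extraction as fx
from aplysia_hill.feature_extraction import (
    EpisodeTrace,
    ProtocolError,
    StiffnessRegressionPoint,
    WindowError,
)


def make_isometric_trace(force_fn, fs=100.0, duration=40.0, on=25.0, off=30.0,
                         protocol="force_frequency", freq=26.0, L=16.0):
    t = np.arange(int(duration * fs) + 1) / fs
    stim = np.where((t >= on) & (t < off), freq, 0.0)
    return EpisodeTrace(
        time=t,
        length=np.full(t.size, L),
        force=force_fn(t),
        stim_freq=stim,
        protocol=protocol,
        stim_onset=on,
        stim_offset=off,
    )


class TestForceFrequencyExtraction:
    def test_constant_force_gives_zero_active(self):
        tr = make_isometric_trace(lambda t: np.full(t.size, 3.0))
        pt = fx.extract_ff_point(tr)
        assert pt.active_force == pytest.approx(0.0, abs=1e-12)
        assert pt.f_stim == 26.0

    def test_all_zero_trace(self):
        tr = make_isometric_trace(lambda t: np.zeros(t.size))
        assert fx.extract_ff_point(tr).active_force == 0.0

    def test_step_response_recovers_amplitude(self):
        # baseline 0.5 N, stimulation adds a 1.2 N plateau
        tr = make_isometric_trace(
            lambda t: 0.5 + np.where((t >= 25) & (t < 30), 1.2, 0.0)
        )
        pt = fx.extract_ff_point(tr)
        assert pt.active_force == pytest.approx(1.2, rel=1e-6)

    def test_insufficient_pre_stimulation_data(self):
        tr = make_isometric_trace(lambda t: np.zeros(t.size), duration=20, on=10, off=15)
        with pytest.raises(WindowError):
            fx.extract_ff_point(tr)

    def test_normalization_maps_max_to_one(self):
        pts = [fx.FFPoint(f, F) for f, F in [(10, 1.0), (20, 2.0), (30, 4.0)]]
        out = fx.normalize_ff_series(pts)
        assert [p.u_f for p in out] == pytest.approx([0.25, 0.5, 1.0])
        single = fx.normalize_ff_series([fx.FFPoint(26, 1.7)])
        assert single[0].u_f == 1.0

    def test_degenerate_normalization(self):
        with pytest.raises(ValueError):
            fx.normalize_ff_series([fx.FFPoint(10, 0.0), fx.FFPoint(20, -0.1)])


class TestLengthTensionExtraction:
    def test_passive_and_active_windows(self):
        # passive plateau 0.4 N; stimulation adds 1.0 N
        tr = make_isometric_trace(
            lambda t: 0.4 + np.where((t >= 25) & (t < 30), 1.0, 0.0),
            protocol="length_tension",
        )
        pt = fx.extract_lt_point(tr)
        assert pt.passive_force == pytest.approx(0.4, rel=1e-6)
        assert pt.active_force == pytest.approx(1.0, rel=1e-6)

    def test_zero_response_episode(self):
        tr = make_isometric_trace(
            lambda t: np.full(t.size, 0.7), protocol="length_tension"
        )
        pt = fx.extract_lt_point(tr)
        assert pt.active_force == pytest.approx(0.0, abs=1e-12)
        assert pt.passive_force == pytest.approx(0.7)

    def test_two_pass_normalization_peak_maps_to_unit(self):
        pts = [
            fx.LTPoint(l_mt=15.0, active_force=0.8, passive_force=0.0),
            fx.LTPoint(l_mt=18.0, active_force=1.6, passive_force=0.1),
            fx.LTPoint(l_mt=21.0, active_force=1.1, passive_force=0.5),
        ]
        out, F_mto, L_mto = fx.normalize_lt_series(pts)
        assert F_mto == 1.6 and L_mto == 18.0
        peak = out[1]
        assert peak.l_mt_norm == 1.0 and peak.lt_active == 1.0
        assert out[2].f_pe_norm == pytest.approx(0.5 / 1.6)

    def test_missing_stimulation_metadata(self):
        tr = make_isometric_trace(lambda t: np.zeros(t.size))
        tr.stim_onset = None
        with pytest.raises(ProtocolError):
            fx.extract_lt_point(tr)


def make_ramp_pair(fce_fn, fpe_fn=None, fs=1000.0, V=-2.0, L0=16.0,
                   ramp_start=5.0, ramp_dur=0.5, passive_ramp_start=2.0):
    """Active/passive isokinetic pair with prescribed CE and passive forces.

    The passive episode's ramp starts at a different wall-clock time than
    the active one, so length-based matching is actually exercised.
    """
    half = abs(V) * ramp_dur / 2

    def build(start, is_active):
        dur = start + ramp_dur + 2.0
        t = np.arange(int(dur * fs) + 1) / fs
        L = np.full(t.size, L0 - np.sign(V) * half)
        in_ramp = (t >= start) & (t <= start + ramp_dur)
        L[in_ramp] = L[in_ramp][0] + V * (t[in_ramp] - start)
        L[t > start + ramp_dur] = L0 + np.sign(V) * half
        fpe = fpe_fn(L) if fpe_fn else np.zeros(t.size)
        force = fpe + (fce_fn(t, start) if is_active else 0.0)
        stim = np.where(is_active, 26.0, 0.0) * np.ones(t.size)
        return EpisodeTrace(
            time=t, length=L, force=force, stim_freq=stim,
            protocol="force_velocity_active" if is_active else "force_velocity_passive",
            stim_onset=0.0 if is_active else None,
            stim_offset=dur if is_active else None,
            t_ramp_start=start, t_ramp_end=start + ramp_dur, V_mt=V,
        )

    return build(passive_ramp_start, False), build(ramp_start, True)


class TestRiseSlope:
    def test_exact_for_polynomial_force(self):
        # F_CE quartic in time: the fitted quartic is exact, and so is
        # its endpoint derivative
        coeffs = [0.3, -0.2, 0.5, 1.0, 0.2]
        passive, active = make_ramp_pair(
            lambda t, s: np.polyval(coeffs, t - s)
        )
        te = active.t_ramp_end
        slope, G = fx.active_force_rise_slope(active, passive)
        expected = np.polyval(np.polyder(np.array(coeffs)), te - active.t_ramp_start)
        assert slope == pytest.approx(expected, rel=1e-6)

    def test_linear_force_returns_slope(self):
        passive, active = make_ramp_pair(lambda t, s: 2.5 * (t - s))
        slope, _ = fx.active_force_rise_slope(active, passive)
        assert slope == pytest.approx(2.5, rel=1e-9)

    def test_passive_matched_by_length_not_time(self):
        # passive force depends only on length; with different ramp start
        # times, time-based matching would fail while length-based works
        fpe = lambda L: 0.3 * (L - 15.0)
        passive, active = make_ramp_pair(
            lambda t, s: 1.5 * (t - s), fpe_fn=fpe,
            ramp_start=6.0, passive_ramp_start=1.0,
        )
        slope, _ = fx.active_force_rise_slope(active, passive)
        # the passive contribution (linear in L, i.e. in t during the
        # ramp) must be fully removed: remaining slope is the CE's
        assert slope == pytest.approx(1.5, rel=1e-3)

    def test_underdetermined_ramp(self):
        passive, active = make_ramp_pair(lambda t, s: t - s, fs=4.0)
        with pytest.raises(WindowError):
            fx.active_force_rise_slope(active, passive)


class TestStiffnessRegression:
    def test_two_point_line_recovers_exactly(self):
        K, F_mto, L_mto = 7.0, 2.0, 20.0
        pts = [
            StiffnessRegressionPoint(V_mt=v, dF_dt=K * F_mto / L_mto * v, G=np.zeros(5))
            for v in (-2.0, 3.0)
        ]
        K_est, diag = fx.estimate_series_stiffness(pts, F_mto, L_mto)
        assert K_est == pytest.approx(K, rel=1e-12)
        assert diag["intercept_N_per_s"] == pytest.approx(0.0, abs=1e-12)

    def test_intercept_reported_not_constrained(self):
        pts = [
            StiffnessRegressionPoint(V_mt=v, dF_dt=2.0 * v + 0.5, G=np.zeros(5))
            for v in (-1.0, 0.0, 1.0, 2.0)
        ]
        K_est, diag = fx.estimate_series_stiffness(pts, 1.0, 1.0)
        assert K_est == pytest.approx(2.0)
        assert diag["intercept_N_per_s"] == pytest.approx(0.5)

    def test_identical_velocities_rejected(self):
        pts = [
            StiffnessRegressionPoint(V_mt=1.0, dF_dt=x, G=np.zeros(5))
            for x in (0.5, 0.7)
        ]
        with pytest.raises(ValueError):
            fx.estimate_series_stiffness(pts, 1.0, 1.0)


class TestFVPointDegenerateCases:
    def test_mismatched_velocities_rejected(self):
        passive, active = make_ramp_pair(lambda t, s: t - s)
        passive.V_mt = -1.0
        with pytest.raises(ProtocolError):
            fx.extract_fv_point(active, passive, [0, 0, 0, 1], 10.0, 18.0)

    def test_isometric_consistency(self):
        # force at ramp end equals the corrected isometric force with a
        # flat rise: the ratio must be 1 and the velocity ~ the imposed one
        fpe = lambda L: np.zeros_like(L)
        passive, active = make_ramp_pair(
            lambda t, s: np.full(t.size if hasattr(t, "size") else 1, 1.2),
            fpe_fn=fpe, V=-0.5,
        )
        B = [0.0, 0.0, 0.0, 1.0]  # flat LT: no length correction
        pt = fx.extract_fv_point(active, passive, B, 10.0, 18.0)
        assert pt.fv_ratio == pytest.approx(1.0, rel=1e-6)
        assert pt.v_m_norm == pytest.approx(0.5 / 18.0, rel=1e-3)


class TestEpisodeIO:
    def test_round_trip(self, tmp_path):
        tr = make_isometric_trace(lambda t: np.sin(t), fs=50.0)
        fx.write_episode_csv(tr, tmp_path / "ep.csv")
        back = fx.read_episode_csv(tmp_path / "ep.csv")
        assert np.allclose(back.force, tr.force)
        assert back.protocol == tr.protocol
        assert back.stim_onset == tr.stim_onset

    def test_non_finite_reported_with_line_number(self, tmp_path):
        tr = make_isometric_trace(lambda t: np.zeros(t.size), fs=50.0)
        tr.force[3] = np.nan
        fx.write_episode_csv(tr, tmp_path / "bad.csv")
        with pytest.raises(ValueError, match="line 5"):
            fx.read_episode_csv(tmp_path / "bad.csv")

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            EpisodeTrace(
                time=np.array([0.0, 1.0, 1.5]),  # non-uniform
                length=np.zeros(3),
                force=np.zeros(3),
                stim_freq=np.zeros(3),
                protocol="force_frequency",
            )
        with pytest.raises(ValueError):
            EpisodeTrace(
                time=np.array([0.0, 0.5, 1.0]),
                length=np.zeros(3),
                force=np.zeros(3),
                stim_freq=np.zeros(3),
                protocol="force_frequency",
                stim_onset=5.0,
                stim_offset=2.0,
            )
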
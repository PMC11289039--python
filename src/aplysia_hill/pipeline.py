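"""End-to-end characterization: episode traces in, fitted model out.

Mirrors the experimental workflow: the length--tension protocol yields the
active cubic (B) and passive exponential (C); the force--velocity protocol
yields the series stiffness (K_t), the FV hyperbolas (D) and their inverse
(E); the series-elasticity shift of the LT data yields the CE-coordinate
cubic (Y); the force--frequency protocol yields the drive sigmoid (A); and
the activation parameters are optimized against the isometric
force--frequency traces.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import feature_extraction as fx
from . import fitting
from .feature_extraction import EpisodeTrace
from .model_core import HillModelParameters
from .simulator import DriveSignal

__all__ = [
    "characterize_force_frequency",
    "characterize_length_tension",
    "characterize_force_velocity",
    "characterize_muscle",
]


def characterize_force_frequency(traces: Sequence[EpisodeTrace]) -> dict:
    """Force--frequency points and sigmoid fit from isometric episodes."""
    points = [fx.extract_ff_point(tr) for tr in traces]
    points = fx.normalize_ff_series(points)
    fit = fitting.fit_force_frequency(
        [p.f_stim for p in points], [p.u_f for p in points]
    )
    return {"points": points, "A": fit.coefficients, "fit": fit}


def characterize_length_tension(traces: Sequence[EpisodeTrace]) -> dict:
    """Length--tension fits from isometric episodes at stepped lengths.

    Conditioning episodes (tagged by the protocol; the first two length
    steps) are excluded from fitting. Returns the constrained active cubic
    B, the passive exponential C with its zero threshold, and the
    per-muscle normalization constants.
    """
    fit_traces = [tr for tr in traces if not tr.meta.get("conditioning", False)]
    raw = [fx.extract_lt_point(tr) for tr in fit_traces]
    points, F_mto_e, L_mto_e = fx.normalize_lt_series(raw)
    b_fit = fitting.fit_active_lt_constrained(
        [p.l_mt_norm for p in points], [p.lt_active for p in points]
    )
    c_fit = fitting.fit_passive_lt(
        [p.l_mt_norm for p in points], [p.f_pe_norm for p in points]
    )
    return {
        "points": points,
        "B": b_fit.coefficients,
        "C": c_fit.coefficients,
        "l_pe_threshold": c_fit.diagnostics["threshold"],
        "F_mto_e": F_mto_e,
        "L_mto_e": L_mto_e,
        "b_fit": b_fit,
        "c_fit": c_fit,
    }


def _pair_fv_traces(
    traces: Sequence[EpisodeTrace],
) -> list[tuple[EpisodeTrace, EpisodeTrace]]:
    """Match passive and active isokinetic episodes by ramp velocity."""
    passive = {
        round(tr.V_mt, 9): tr
        for tr in traces
        if tr.protocol == "force_velocity_passive"
    }
    pairs = []
    for tr in traces:
        if tr.protocol != "force_velocity_active":
            continue
        key = round(tr.V_mt, 9)
        if key not in passive:
            raise fx.ProtocolError(f"no passive episode matches V_mt = {tr.V_mt}")
        pairs.append((passive[key], tr))
    return pairs


def characterize_force_velocity(
    traces: Sequence[EpisodeTrace],
    B,
    F_mto: float,
    L_mto: float,
) -> dict:
    """Stiffness and force--velocity fits from isokinetic episode pairs.

    The stiffness regression runs over every pair's active-force rise
    slope at ramp onset; the resulting K_t then feeds the CE-velocity
    correction of each FV point, and the D (forward) and E (inverse)
    families are fitted from the points.
    """
    pairs = _pair_fv_traces(traces)
    if not pairs:
        raise fx.ProtocolError("no matched passive/active pairs found")

    # Stiffness slopes are taken at the ramp start: the spring-rate
    # relation dF_CE/dt = K_t (V_mt - V_m) reduces to K_t V_mt only while
    # the CE has not yet accelerated, i.e. immediately after ramp onset.
    stiff_points = []
    for passive, active in pairs:
        T = float(active.t_ramp_end - active.t_ramp_start)
        slope, G = fx.active_force_rise_slope(
            active,
            passive,
            eval_time=float(active.t_ramp_start),
            window_s=min(T, max(T / 4, 0.1)),
        )
        stiff_points.append(
            fx.StiffnessRegressionPoint(V_mt=active.V_mt, dF_dt=slope, G=G)
        )
    K_t, k_diag = fx.estimate_series_stiffness(stiff_points, F_mto, L_mto)

    fv_points = [
        fx.extract_fv_point(active, passive, B, K_t, L_mto)
        for passive, active in pairs
    ]
    v = np.array([p.v_m_norm for p in fv_points])
    fv = np.array([p.fv_ratio for p in fv_points])
    d_fit = fitting.fit_fv_piecewise(v, fv)
    # The inverse map is fitted to the forward fit's own curve rather
    # than to the scattered points: the hyperbolas pass through (0, 1)
    # structurally, so this pins the inverse curve's isometric zero
    # crossing and its slope there — both of which float badly on
    # extrapolation when the double exponential is fitted to the points
    # alone (the protocol has no samples between the slowest shortening
    # and lengthening ramps).
    e_fit = fitting.refit_inverse_fv_from_forward(
        d_fit.coefficients, v_range=(float(v.min()), float(v.max()))
    )
    return {
        "points": fv_points,
        "stiffness_points": stiff_points,
        "K_t": K_t,
        "K_t_diagnostics": k_diag,
        "D": d_fit.coefficients,
        "E": e_fit.coefficients,
        "d_fit": d_fit,
        "e_fit": e_fit,
    }


def characterize_muscle(
    ff_traces: Sequence[EpisodeTrace],
    lt_traces: Sequence[EpisodeTrace],
    fv_traces: Sequence[EpisodeTrace],
    fit_activation: bool = True,
    activation_x0=(1.0, 0.5, 0.5, 2.0),
    activation_episodes: int = 1,
) -> HillModelParameters:
    """Run the full characterization pipeline on one muscle's episodes.

    Order matters: LT gives B/C and the normalization scales, FV gives
    K_t/D/E, the series-elasticity shift of the LT points gives Y, FF
    gives A, and (optionally) the activation parameters are fitted to the
    isometric force--frequency traces.
    """
    lt = characterize_length_tension(lt_traces)
    F_mto, L_mto = lt["F_mto_e"], lt["L_mto_e"]
    fv = characterize_force_velocity(fv_traces, lt["B"], F_mto, L_mto)

    # Series-elasticity shift and unconstrained cubic refit in CE
    # coordinates. The (1,1)-stationarity constraints apply to the
    # total-length fit only: after the shift the peak no longer sits at
    # exactly 1, and forcing it there distorts the curve.
    points = lt["points"]
    l_m = fitting.shift_to_contractile_length(
        np.array([p.l_mt_norm for p in points]),
        np.array([p.lt_active for p in points]),
        fv["K_t"],
    )
    Y = np.polyfit(l_m, np.array([p.lt_active for p in points]), 3)

    ff = characterize_force_frequency(ff_traces)

    # Fixed-point correction of the force scale: the measured peak active
    # force is not the CE's peak capacity — at isometric equilibrium the
    # series spring displaces the CE off its optimum, so the model's
    # simulated peak is f* = Y(1 - f*/K_t) < 1 of its F_mto. Identifying
    # F_mto with the measured peak therefore yields a model ~7% weaker
    # than the muscle it was fitted to. Dividing by f* (and rescaling the
    # force-normalized stiffness to keep the dimensional spring constant)
    # makes the fitted model reproduce the forces it was fitted from.
    from scipy.optimize import brentq

    f_star = brentq(
        lambda f: f
        - float(np.polyval(Y, 1.0 - f / fv["K_t"])),
        0.2,
        1.2,
    )
    F_mto_model = F_mto / f_star
    K_t_model = fv["K_t"] * f_star

    params = HillModelParameters(
        F_mto=F_mto_model,
        L_mto=L_mto,
        L_0=float(lt_traces[0].length[0]) if lt_traces else L_mto,
        K_t=K_t_model,
        A=ff["A"],
        B=lt["B"],
        Y=Y,
        C=lt["C"],
        l_pe_threshold=lt["l_pe_threshold"],
        D=fv["D"],
        E=fv["E"],
        tau=1.0,
        beta=0.5,
        a0=0.5,
        g=2.0,
    )
    if fit_activation:
        act = fit_activation_from_traces(
            params, ff_traces, x0=activation_x0, n_episodes=activation_episodes
        )
        tau, beta, a0, g = act.coefficients
        params = params.replace(tau=float(tau), beta=float(beta), a0=float(a0), g=float(g))
    return params


def fit_activation_from_traces(
    params: HillModelParameters,
    ff_traces: Sequence[EpisodeTrace],
    x0=(1.0, 0.5, 0.5, 2.0),
    n_episodes: int = 1,
    mse_rate_hz: float = 10.0,
) -> fitting.FitResult:
    """Fit activation parameters against isometric episode traces.

    Both a rise and a decay phase are needed (the relaxation ratio only
    shapes the tail). By default only the episode closest to the
    protocol's working saturation frequency (26 Hz, the stimulation used
    throughout the length and velocity experiments) is used: near
    saturation the drive is ~1 regardless of how well the refit sigmoid
    matches the muscle's composed frequency response, so the time
    constants are not asked to compensate for drive-curve misfit at
    intermediate frequencies, and the calibration shares the operating
    point of the rest of the protocol. The measured trace is decimated
    for the error computation. Both knobs are exposed.
    """
    traces = sorted(
        ff_traces, key=lambda tr: abs(float(tr.stim_freq.max()) - 26.0)
    )
    if n_episodes and len(traces) > n_episodes:
        traces = traces[:n_episodes]
    episodes = []
    for tr in traces:
        drive = DriveSignal(
            np.array([tr.time[0], tr.stim_onset, tr.stim_offset]),
            np.array([0.0, float(tr.stim_freq.max()), 0.0]),
            mode="frequency",
        )
        step = max(int(round(tr.fs / mse_rate_hz)), 1)
        # the informative window: a little pre-stimulation baseline, the
        # rise, and enough tail to pin the relaxation time constant
        keep = (tr.time >= tr.stim_onset - 2.0) & (tr.time <= tr.stim_offset + 15.0)
        t_meas = tr.time[keep][::step]
        f_meas = tr.force[keep][::step]
        episodes.append((drive, (tr.time, tr.length), t_meas, f_meas))
    return fitting.fit_activation_parameters(params, episodes, x0=x0)
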
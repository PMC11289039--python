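"""Forward simulation of muscle force from imposed length and neural drive.

The muscle state is the pre-scaling activation a' and the normalized
contractile-element (CE) length l_m. At each instant the series spring
carries the CE force, so the force--velocity relationship is inverted to
give the CE velocity from the ratio of spring force to the activation- and
length-scaled isometric capacity. The coupled ODEs

    da'/dt = (u_f - [beta + (1-beta) u_f] a') / tau
    dl_m/dt = -IFV( f_see / (a * LT(l_m)) )

are integrated with an adaptive solver (max step 50 ms by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    HillModelParameters,
    activation_output,
    active_length_tension,
    force_frequency_response,
    inverse_force_velocity,
    passive_length_tension,
    series_elastic_force,
)

__all__ = [
    "MuscleState",
    "DriveSignal",
    "SimulationResult",
    "SimulationError",
    "contractile_velocity",
    "simulate_episode",
    "simulate_isometric_force",
]

# Guards for the algebraic force ratio fed to the inverse force-velocity
# curve: denominator floor, LT floor, and how close the ratio may come to
# the lengthening asymptote 1 + D3 (the inverse diverges there).
_DENOM_EPS = 1e-6
_LT_FLOOR = 1e-3
_R_MARGIN = 1e-3


class SimulationError(RuntimeError):
    """Integration failure, carrying the time at which the solver stopped."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.6g} s)")
        self.t_fail = t_fail


@dataclass
class MuscleState:
    """Simulator state: pre-scaling activation and normalized CE length."""

    a_prime: float
    l_m_norm: float


@dataclass
class DriveSignal:
    """Sampled neural input.

    ``mode="frequency"`` treats values as stimulation frequencies in Hz,
    mapped through the force--frequency sigmoid; ``mode="drive"`` treats
    them as pre-scaled u_f in [0, 1]. Values are held between samples
    (zero-order hold: stimulation is a held frequency, not a ramp).
    """

    time: np.ndarray
    value: np.ndarray
    mode: str = "frequency"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.mode not in ("frequency", "drive"):
            raise ValueError(f"unknown drive mode {self.mode!r}")
        if self.time.ndim != 1 or self.time.shape != self.value.shape:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("drive time must be strictly increasing")
        if np.any(self.value < 0):
            raise ValueError("drive values must be non-negative")

    def u_f(self, t, A) -> np.ndarray:
        """Neural drive u_f at time t (zero-order hold, then sigmoid)."""
        idx = np.clip(
            np.searchsorted(self.time, np.asarray(t, dtype=float), side="right") - 1,
            0,
            self.time.size - 1,
        )
        raw = self.value[idx]
        if self.mode == "frequency":
            return force_frequency_response(raw, A)
        return np.clip(raw, 0.0, 1.0)

    @classmethod
    def constant(cls, value: float, t_end: float, mode: str = "frequency"):
        return cls(np.array([0.0, t_end]), np.array([value, value]), mode)


@dataclass
class SimulationResult:
    """Dense simulator output sampled at the reporting rate."""

    time: np.ndarray
    force: np.ndarray       # N
    activation: np.ndarray  # a(t) in [0, 1]
    a_prime: np.ndarray
    l_m_norm: np.ndarray
    f_pe: np.ndarray        # normalized passive force
    f_see: np.ndarray       # normalized series-spring (= CE) force


def _length_interpolator(
    length_trajectory, L_mto: float
) -> Callable[[float], float]:
    """Normalize a length input to a callable t -> l_mt (normalized)."""
    if callable(length_trajectory):
        return lambda t: float(length_trajectory(t)) / L_mto
    t_arr, L_arr = (np.asarray(a, dtype=float) for a in length_trajectory)
    if np.any(np.diff(t_arr) <= 0):
        raise ValueError("length trajectory time must be strictly increasing")
    return lambda t: float(np.interp(t, t_arr, L_arr)) / L_mto


def contractile_velocity(
    params: HillModelParameters,
    state: MuscleState,
    l_mt_norm: float,
    a: float,
) -> float:
    """CE velocity (shortening positive) from the force-balance ratio.

    The SEE force must equal a * LT(l_m) * FV(v_m); solving for v_m uses
    the fitted inverse-FV curve on r = f_see / (a * LT(l_m)). The ratio is
    clamped to [0, (1 + D3)(1 - margin)] and the denominator floored so the
    map stays total: an unloaded active muscle shortens at the unloaded
    maximum, while a loaded inactive muscle yields at the lengthening
    asymptote.
    """
    f_see = series_elastic_force(l_mt_norm - state.l_m_norm, params.K_t)
    lt = max(active_length_tension(state.l_m_norm, params.Y), _LT_FLOOR)
    denom = max(a * lt, _DENOM_EPS)
    r_max = (1.0 + params.D[2]) * (1.0 - _R_MARGIN)
    r = min(max(f_see / denom, 0.0), r_max)
    return inverse_force_velocity(r, params.E)


def simulate_episode(
    params: HillModelParameters,
    drive: DriveSignal,
    length_trajectory,
    t_span: Optional[tuple[float, float]] = None,
    initial_state: Optional[MuscleState] = None,
    max_step: float = 0.05,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "BDF",
    reporting_rate: float = 500.0,
) -> SimulationResult:
    """Integrate the muscle model over an episode.

    Parameters
    ----------
    params : HillModelParameters
    drive : DriveSignal
        Stimulation frequency (Hz) or pre-scaled drive, held between samples.
    length_trajectory : callable or (time, length) pair
        Imposed total muscle length L_mt in mm; sampled trajectories are
        linearly interpolated.
    t_span : (t0, t1), optional
        Defaults to the drive's time span.
    initial_state : MuscleState, optional
        Defaults to an unstretched SEE (l_m = l_mt(t0)) and a' = a0, so
        the initial activation output is zero.
    max_step : float
        Maximum solver step, s. Default 50 ms.
    reporting_rate : float
        Output sampling rate, Hz.

    Returns
    -------
    SimulationResult
        Dense output; ``force = F_mto * (f_pe + f_see)`` at every sample.
    """
    if t_span is None:
        t_span = (float(drive.time[0]), float(drive.time[-1]))
    t0, t1 = map(float, t_span)
    l_mt = _length_interpolator(length_trajectory, params.L_mto)

    if initial_state is None:
        initial_state = MuscleState(a_prime=params.a0, l_m_norm=l_mt(t0))
    if not initial_state.l_m_norm > 0:
        raise ValueError("initial l_m_norm must be positive")

    def rhs(t, y):
        a_prime, l_m = y
        u = float(drive.u_f(t, params.A))
        da = (u - (params.beta + (1.0 - params.beta) * u) * a_prime) / params.tau
        a = activation_output(a_prime, params.g, params.a0)
        v_m = contractile_velocity(
            params, MuscleState(a_prime, l_m), l_mt(t), a
        )
        return [da, -v_m]

    n_out = max(int(round((t1 - t0) * reporting_rate)), 2)
    t_eval = np.linspace(t0, t1, n_out + 1)

    # the drive is held between samples and the length is piecewise
    # linear, so the RHS has kinks at their knots; integrating segment by
    # segment keeps the solver from stepping across a discontinuity
    knots = [drive.time]
    if not callable(length_trajectory):
        knots.append(np.asarray(length_trajectory[0], dtype=float))
    breaks = np.unique(np.concatenate(knots))
    breaks = breaks[(breaks > t0) & (breaks < t1)]
    edges = np.concatenate([[t0], breaks, [t1]])

    t_out, a_out, l_out = [], [], []
    y = [initial_state.a_prime, initial_state.l_m_norm]
    for a_edge, b_edge in zip(edges[:-1], edges[1:]):
        pts = t_eval[(t_eval >= a_edge) & (t_eval <= b_edge)]
        # always evaluate at the segment end so the next segment resumes
        # from the true final state, not the last reporting sample
        pts_ext = pts if pts.size and pts[-1] == b_edge else np.append(pts, b_edge)
        sol = solve_ivp(
            rhs,
            (a_edge, b_edge),
            y,
            method=method,
            t_eval=pts_ext,
            max_step=max_step,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE solver failed: {sol.message}",
                float(sol.t[-1]) if sol.t.size else a_edge,
            )
        n_keep = pts.size
        if n_keep:
            t_out.append(sol.t[:n_keep] if pts_ext.size > pts.size else sol.t)
            a_out.append(sol.y[0][: t_out[-1].size])
            l_out.append(sol.y[1][: t_out[-1].size])
        y = [float(sol.y[0][-1]), float(sol.y[1][-1])]

    t_all = np.concatenate(t_out)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all = t_all[keep]
    a_prime = np.concatenate(a_out)[keep]
    l_m = np.concatenate(l_out)[keep]
    l_mt_arr = np.array([l_mt(t) for t in t_all])
    f_pe = np.asarray(
        passive_length_tension(l_mt_arr, params.C, params.l_pe_threshold)
    )
    f_see = np.asarray(series_elastic_force(l_mt_arr - l_m, params.K_t))
    activation = np.asarray(activation_output(a_prime, params.g, params.a0))
    force = params.F_mto * (f_pe + f_see)
    return SimulationResult(
        time=t_all,
        force=force,
        activation=activation,
        a_prime=a_prime,
        l_m_norm=l_m,
        f_pe=f_pe,
        f_see=f_see,
    )


def _segment_activation(u: float, a_start: float, params) -> tuple[float, float]:
    """Fixed point and rate of the activation ODE under a held drive."""
    k = (params.beta + (1.0 - params.beta) * u) / params.tau
    return u / (params.beta + (1.0 - params.beta) * u), k


def simulate_isometric_force(
    params: HillModelParameters,
    drive: DriveSignal,
    L_mt_mm: float,
    t_eval: np.ndarray,
) -> np.ndarray:
    """Force of an isometric episode, using the analytic activation solution.

    Under a held (zero-order-hold) drive the activation ODE is a chain of
    exponentials with segment-wise fixed points, so only the series-spring
    force needs numerical integration — a one-dimensional ODE, and only
    over the spans where the output activation is positive. Outside those
    spans the contractile element carries no force: the spring force
    relaxes at the clamped maximum lengthening rate and then stays at
    zero, so the muscle force is the passive curve alone.

    Matches :func:`simulate_episode` on isometric episodes at a fraction
    of the cost; used by the activation-parameter fit, where the force
    model is evaluated hundreds of times.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    l_mt = L_mt_mm / params.L_mto
    f_pe = float(passive_length_tension(l_mt, params.C, params.l_pe_threshold))

    # piecewise-exponential a'(t) over the drive's hold segments
    u_vals = (
        force_frequency_response(drive.value, params.A)
        if drive.mode == "frequency"
        else np.clip(drive.value, 0.0, 1.0)
    )
    t_breaks = np.concatenate([drive.time, [max(t_eval[-1], drive.time[-1]) + 1.0]])
    seg_start_a = np.empty(drive.time.size)
    seg_ss = np.empty(drive.time.size)
    seg_k = np.empty(drive.time.size)
    u0 = float(u_vals[0])
    a_cur = u0 / (params.beta + (1.0 - params.beta) * u0)  # rest equilibrium
    for j in range(drive.time.size):
        ss, k = _segment_activation(float(u_vals[j]), a_cur, params)
        seg_start_a[j], seg_ss[j], seg_k[j] = a_cur, ss, k
        a_cur = ss + (a_cur - ss) * np.exp(-k * (t_breaks[j + 1] - t_breaks[j]))

    def a_prime(t):
        j = np.clip(np.searchsorted(drive.time, t, side="right") - 1, 0, drive.time.size - 1)
        return seg_ss[j] + (seg_start_a[j] - seg_ss[j]) * np.exp(
            -seg_k[j] * (t - drive.time[j])
        )

    def a_of(t):
        return np.clip(params.g * (a_prime(t) - params.a0), 0.0, 1.0)

    # spans where a > 0: find threshold crossings of a' against a0 per segment
    crossings = []
    for j in range(drive.time.size):
        a_s, ss, k = seg_start_a[j], seg_ss[j], seg_k[j]
        lo_t, hi_t = t_breaks[j], t_breaks[j + 1]
        if (a_s - params.a0) * (ss - params.a0) < 0 and a_s != ss:
            frac = (params.a0 - ss) / (a_s - ss)
            if 0 < frac <= 1:
                tc = lo_t - np.log(frac) / k
                if lo_t < tc < hi_t:
                    crossings.append(tc)
    t_lo, t_hi = float(t_eval[0]), float(t_eval[-1])
    knots = sorted({t_lo, t_hi, *[c for c in crossings if t_lo < c < t_hi]})
    spans = []
    for a, b in zip(knots[:-1], knots[1:]):
        mid = 0.5 * (a + b)
        if a_of(mid) > 0:
            spans.append((a, b))

    f_see = np.zeros_like(t_eval)
    lt_floor = _LT_FLOOR
    r_max = (1.0 + params.D[2]) * (1.0 - _R_MARGIN)
    v_yield = float(inverse_force_velocity(r_max, params.E))  # most negative

    def f_rhs(t, y):
        f = y[0]
        lt = max(active_length_tension(l_mt - f / params.K_t, params.Y), lt_floor)
        denom = max(float(a_of(t)) * lt, _DENOM_EPS)
        r = min(max(f / denom, 0.0), r_max)
        return [params.K_t * inverse_force_velocity(r, params.E)]

    f_carry = 0.0
    t_carry = None
    for a, b in spans:
        # force left over from a previous span decays at the clamped
        # lengthening rate while a = 0
        if t_carry is not None and f_carry > 1e-9:
            decay = params.K_t * abs(v_yield)
            seg = (t_eval > t_carry) & (t_eval <= a)
            f_see[seg] = np.maximum(f_carry - decay * (t_eval[seg] - t_carry), 0.0)
            f_carry = max(f_carry - decay * (a - t_carry), 0.0)
        mask = (t_eval >= a) & (t_eval <= b)
        pts = t_eval[mask]
        # evaluate at the span end as well, so the carried state is the
        # true final state rather than the last reporting sample
        pts_ext = pts if pts.size and pts[-1] == b else np.append(pts, b)
        sol = solve_ivp(
            f_rhs,
            (a, b),
            [f_carry],
            method="LSODA",
            t_eval=pts_ext,
            max_step=0.05,
            rtol=1e-6,
            atol=1e-9,
        )
        if not sol.success:
            raise SimulationError(f"isometric fast path failed: {sol.message}", a)
        if pts.size:
            f_see[mask] = sol.y[0][: pts.size]
        f_carry = float(sol.y[0][-1])
        t_carry = b
    if t_carry is not None and f_carry > 1e-9:
        decay = params.K_t * abs(v_yield)
        seg = t_eval > t_carry
        f_see[seg] = np.maximum(f_carry - decay * (t_eval[seg] - t_carry), 0.0)

    return params.F_mto * (f_pe + f_see)
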
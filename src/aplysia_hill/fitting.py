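"""Least-squares fitting of every curve family of the muscle model.

The active length--tension cubic is a linearly-constrained linear
least-squares problem (equality constraints pin the stationary point to
(1, 1); inequality constraints keep the cubic concave over the data range)
and is solved exactly by active-set enumeration over its two inequality
constraints. The sigmoid, exponential and hyperbolic families are fitted
with deterministic multi-start nonlinear least squares. Activation
parameters are fitted by simplex search on the simulated-vs-measured force
error. No randomness anywhere: identical inputs give identical fits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import lstsq, null_space
from scipy.optimize import curve_fit, minimize

from . import simulator
from .model_core import HillModelParameters, force_velocity

__all__ = [
    "FitResult",
    "FitError",
    "IdentifiabilityWarning",
    "fit_force_frequency",
    "fit_active_lt_constrained",
    "shift_to_contractile_length",
    "fit_passive_lt",
    "fit_fv_piecewise",
    "fit_inverse_fv",
    "fit_activation_parameters",
    "refit_inverse_fv_from_forward",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from every start."""


class IdentifiabilityWarning(UserWarning):
    """Emitted when the data cannot constrain all requested parameters."""


@dataclass
class FitResult:
    """Outcome of a curve fit.

    ``diagnostics`` carries family-specific extras (constraint residuals
    for the cubic, per-start losses for multi-start fits, threshold for the
    passive exponential).
    """

    coefficients: np.ndarray
    rss: float
    n_points: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def _finite_xy(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


# -- force-frequency sigmoid --------------------------------------------------

_SIGMOID_STARTS = [
    np.array([1.0, a2, a3, a4])
    for a2 in (1.0, 5.0, 10.0)
    for a3 in (0.1, 0.3, 1.0)
    for a4 in (5.0, 10.0, 15.0)
]


def fit_force_frequency(f_stim, u_f) -> FitResult:
    """Fit the 4-parameter force--frequency sigmoid to normalized forces.

    Multi-start Levenberg-Marquardt over a fixed grid of initial guesses;
    the best (lowest-RSS) converged start wins. The individual coefficients
    trade off against each other; curve values are the reliable output.
    """
    f, u = _finite_xy(f_stim, u_f)
    if f.size < 4:
        raise FitError(f"need at least 4 points, got {f.size}")

    def model(x, a1, a2, a3, a4):
        return a1 / (a1 + a2 * np.exp(-a3 * (x - a4)))

    best = None
    per_start = []
    for p0 in _SIGMOID_STARTS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, f, u, p0=p0, maxfev=5000)
            rss = float(np.sum((model(f, *popt) - u) ** 2))
            per_start.append((list(p0), rss))
            if np.all(np.isfinite(popt)) and (best is None or rss < best[1]):
                best = (popt, rss)
        except RuntimeError:
            per_start.append((list(p0), np.inf))
    if best is None:
        raise FitError(f"sigmoid fit failed from all {len(_SIGMOID_STARTS)} starts")
    popt, rss = best
    return FitResult(
        coefficients=np.asarray(popt),
        rss=rss,
        n_points=f.size,
        converged=True,
        diagnostics={"per_start_rss": per_start},
    )


# -- constrained active length-tension cubic ----------------------------------

def _solve_equality_ls(X, y, Aeq, beq):
    """Least squares min ||Xb - y|| s.t. Aeq b = beq, via nullspace."""
    b_part, *_ = lstsq(Aeq, beq)
    Z = null_space(Aeq)
    if Z.size == 0:
        return b_part
    z, *_ = lstsq(X @ Z, y - X @ b_part)
    return b_part + Z @ z


def fit_active_lt_constrained(l_norm, lt) -> FitResult:
    """Constrained cubic fit of the active length--tension relationship.

    Minimizes the squared residual of ``B1 l^3 + B2 l^2 + B3 l + B4``
    subject to the cubic passing through (1, 1) with zero slope there
    (equalities) and being concave at both ends of the data range
    (inequalities ``6 B1 l + 2 B2 <= 0`` at min and max l). Solved exactly
    by enumerating active sets of the two inequality constraints.
    """
    l, y = _finite_xy(l_norm, lt)
    if l.size < 4:
        raise FitError(f"need at least 4 points, got {l.size}")

    X = np.vander(l, 4)  # columns l^3, l^2, l, 1
    Aeq = np.array([[1.0, 1.0, 1.0, 1.0], [3.0, 2.0, 1.0, 0.0]])
    beq = np.array([1.0, 0.0])
    lo, hi = float(l.min()), float(l.max())
    G = np.array([[6.0 * lo, 2.0, 0.0, 0.0], [6.0 * hi, 2.0, 0.0, 0.0]])

    best = None
    for active in itertools.chain.from_iterable(
        itertools.combinations((0, 1), k) for k in range(3)
    ):
        A_act = np.vstack([Aeq] + [G[i] for i in active])
        b_act = np.concatenate([beq, np.zeros(len(active))])
        if np.linalg.matrix_rank(A_act) < A_act.shape[0]:
            continue
        b = _solve_equality_ls(X, y, A_act, b_act)
        if np.any(G @ b > 1e-9):  # infeasible candidate
            continue
        rss = float(np.sum((X @ b - y) ** 2))
        if best is None or rss < best[1] - 1e-15:
            best = (b, rss)
    assert best is not None, "constraint set is infeasible (cannot happen)"
    b, rss = best
    return FitResult(
        coefficients=b,
        rss=rss,
        n_points=l.size,
        converged=True,
        diagnostics={
            "equality_residual": Aeq @ b - beq,
            "inequality_slack": G @ b,
            "l_range": (lo, hi),
        },
    )


def shift_to_contractile_length(l_mt_norm, f_ce_norm, K_t: float):
    """Shift total-length abscissae to CE length: l_m = l_mt - f_ce/K_t.

    ``f_ce_norm`` is the normalized active force (units of F_mto), so the
    shift is dimensionally a normalized length. Refit the shifted points
    with :func:`fit_active_lt_constrained` to obtain the Y coefficients.
    """
    if K_t <= 0:
        raise ValueError("K_t must be positive")
    l = np.asarray(l_mt_norm, dtype=float)
    f = np.asarray(f_ce_norm, dtype=float)
    return l - f / K_t


# -- passive exponential ------------------------------------------------------

def fit_passive_lt(l_mt_norm, f_pe, min_force_frac: float = 0.01) -> FitResult:
    """Fit ``C1 + C2 * exp(C3*l - C4)`` to passive force data.

    Only points above the zero-force regime (passive force greater than
    ``min_force_frac`` of the maximum) inform the exponential branch. The
    amplitude pair (C2, C4) is redundant (only C2*exp(-C4) matters), so the
    fit uses a 3-parameter form and reports C4 = 0. The zero-crossing
    threshold is the largest length at which the fitted curve crosses zero,
    clipped to the data range; 0.87 is reported if there is no crossing.
    """
    l, y = _finite_xy(l_mt_norm, f_pe)
    if l.size < 4:
        raise FitError(f"need at least 4 points, got {l.size}")
    y_max = float(y.max())
    if y_max <= 0:
        return FitResult(
            coefficients=np.array([0.0, 0.0, 0.0, 0.0]),
            rss=float(np.sum(y**2)),
            n_points=l.size,
            converged=True,
            diagnostics={"threshold": float(l.max()), "degenerate": True},
        )
    mask = y > min_force_frac * y_max
    lf, yf = l[mask], y[mask]
    if lf.size < 4:
        lf, yf = l, y

    def model(x, c1, log_amp, c3):
        return c1 + np.exp(log_amp) * np.exp(c3 * x)

    # moment-based starts: slope of log(y - min) roughly sets c3
    starts = [(-1.0, np.log(y_max) - c3 * lf.max(), c3) for c3 in (0.5, 2.0, 5.0, 10.0)]
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, lf, yf, p0=p0, maxfev=10000)
            rss = float(np.sum((model(lf, *popt) - yf) ** 2))
            if np.all(np.isfinite(popt)) and (best is None or rss < best[1]):
                best = (popt, rss)
        except RuntimeError:
            continue
    if best is None:
        raise FitError("passive exponential fit failed from all starts")
    (c1, log_amp, c3), rss = best
    C = np.array([c1, np.exp(log_amp), c3, 0.0])

    threshold = 0.87
    if c1 < 0 and C[1] > 0 and c3 > 0:
        crossing = (np.log(-c1 / C[1])) / c3
        threshold = float(np.clip(crossing, l.min(), l.max()))
    return FitResult(
        coefficients=C,
        rss=rss,
        n_points=l.size,
        converged=True,
        diagnostics={"threshold": threshold, "degenerate": False},
    )


# -- force-velocity hyperbolas and inverse ------------------------------------

def fit_fv_piecewise(v_m_norm, fv) -> FitResult:
    """Fit the piecewise-hyperbolic force--velocity curve.

    Shortening (v > 0) and lengthening (v < 0) branches are independent
    2-parameter fits with the pole coefficients D2, D4 bounded positive.
    Single-sided data yields a partial fit with the missing branch flagged
    and filled with neutral coefficients (0 amplitude, pole 1).
    """
    v, y = _finite_xy(v_m_norm, fv)
    short_mask = v > 0
    long_mask = v < 0
    D = np.array([0.0, 1.0, 0.0, 1.0])
    missing = []
    rss = 0.0

    def _branch(vs, ys, sign):
        if sign > 0:
            model = lambda x, d1, d2: 1.0 + d1 / (1.0 + d2 / x)
            p0 = (min(ys.min() - 1.0, -0.1), 0.1)
            bounds = ([-1.0, 1e-6], [0.0, 10.0])
        else:
            model = lambda x, d3, d4: 1.0 + d3 / (1.0 - d4 / x)
            p0 = (max(ys.max() - 1.0, 0.1), 0.1)
            bounds = ([0.0, 1e-6], [5.0, 10.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, vs, ys, p0=p0, bounds=bounds, maxfev=10000)
        return popt, float(np.sum((model(vs, *popt) - ys) ** 2))

    if short_mask.sum() >= 2:
        (d1, d2), r = _branch(v[short_mask], y[short_mask], +1)
        D[0], D[1] = d1, d2
        rss += r
    else:
        missing.append("shortening")
    if long_mask.sum() >= 2:
        (d3, d4), r = _branch(v[long_mask], y[long_mask], -1)
        D[2], D[3] = d3, d4
        rss += r
    else:
        missing.append("lengthening")
    if len(missing) == 2:
        raise FitError("no usable points on either side of zero velocity")
    return FitResult(
        coefficients=D,
        rss=rss,
        n_points=v.size,
        converged=True,
        diagnostics={"missing_branches": missing},
    )


def fit_inverse_fv(fv, v_m_norm, weights=None) -> FitResult:
    """Fit the double-exponential inverse force--velocity curve.

    ``v = -E1*exp(E2*(FV - E3)) + E4*exp(E5*FV)``. Deterministic
    multi-start: the stiffness of the lengthening exponential (E2) and the
    shortening decay (E5) are gridded; amplitude/offset starts come from
    the data extremes. Optional per-point ``weights`` multiply the
    residuals.
    """
    x, y = _finite_xy(fv, v_m_norm)
    if x.size < 5:
        raise FitError(f"need at least 5 points, got {x.size}")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)

    def model(fvv, e1, e2, e3, e4, e5):
        return -e1 * np.exp(np.minimum(e2 * (fvv - e3), 50.0)) + e4 * np.exp(
            np.minimum(e5 * fvv, 50.0)
        )

    e3_0 = float(x.max())
    e1_0 = max(float(-y.min()), 0.1)
    v_max = max(float(y.max()), 0.1)
    best = None
    per_start = []
    for e2_0 in (2.0, 6.0, 12.0):
        for e5_0 in (-2.0, -5.0, -8.0):
            e4_0 = v_max * np.exp(-e5_0 * float(x.min()))
            p0 = (e1_0, e2_0, e3_0, e4_0, e5_0)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        model, x, y, p0=p0, sigma=1.0 / w, maxfev=20000
                    )
                rss = float(np.sum(((model(x, *popt) - y) * w) ** 2))
                per_start.append((p0, rss))
                if np.all(np.isfinite(popt)) and (best is None or rss < best[1]):
                    best = (popt, rss)
            except RuntimeError:
                per_start.append((p0, np.inf))
    if best is None:
        raise FitError("inverse force-velocity fit failed from all starts")
    popt, rss = best
    return FitResult(
        coefficients=np.asarray(popt),
        rss=rss,
        n_points=x.size,
        converged=True,
        diagnostics={"per_start_rss": per_start},
    )


def refit_inverse_fv_from_forward(
    D, v_range: tuple[float, float] = (-0.45, 0.45), n: int = 181
) -> FitResult:
    """Fit E to the exact inverse of the forward FV hyperbolas.

    Samples (FV(v), v) on a velocity grid — densified near zero velocity,
    where the hyperbolas are steepest — and fits the double exponential
    with residuals weighted by |dFV/dv|, so the error is controlled in
    force-ratio units. This yields an inverse map consistent with the
    forward curve over the sampled range; it is used to build
    self-consistent simulation models, since independently fitted D and E
    need not invert each other.
    """
    D = np.asarray(D, dtype=float)
    v = np.unique(
        np.concatenate(
            [
                np.linspace(v_range[0], v_range[1], n),
                np.linspace(-0.06, 0.06, n // 2),
            ]
        )
    )
    fv = force_velocity(v, D)
    dfv = np.empty_like(v)
    pos = v >= 0
    dfv[pos] = -D[0] * D[1] / (v[pos] + D[1]) ** 2
    dfv[~pos] = -D[2] * D[3] / (v[~pos] - D[3]) ** 2
    weights = np.clip(np.abs(dfv), 0.05, 20.0)
    return fit_inverse_fv(fv, v, weights=weights)


# -- activation dynamics ------------------------------------------------------

_ACTIVATION_BOUNDS = {
    "tau": (1e-3, 10.0),
    "beta": (1e-3, 1.0),
    "a0": (0.0, 0.999),
    "g": (1e-2, 20.0),
}


def fit_activation_parameters(
    params: HillModelParameters,
    episodes: Sequence[tuple["simulator.DriveSignal", object, np.ndarray, np.ndarray]],
    x0=(1.0, 0.5, 0.5, 2.0),
    maxiter: int = 400,
    reporting_rate: float = 50.0,
) -> FitResult:
    """Fit (tau, beta, a0, g) by matching simulated to measured force.

    Parameters
    ----------
    params : HillModelParameters
        Model with all curve families already fitted; its activation fields
        are ignored and replaced during the search.
    episodes : sequence of (drive, length_trajectory, time, force)
        Isometric episodes; ``time``/``force`` is the measured trace the
        simulation is compared against (mean squared error, simulated force
        interpolated onto the measured time base).
    x0 : tuple
        Deterministic simplex start (tau, beta, a0, g).

    Notes
    -----
    beta only shapes the relaxation tail, so episodes must include a
    stimulation-off phase; rise-only data triggers an identifiability
    warning. a0 and g trade off against each other and are best judged
    through the composed activation curve, not individually.
    """
    episodes = list(episodes)
    if not episodes:
        raise FitError("no episodes provided")
    has_excitation = any(np.any(d.value > 0) for d, *_ in episodes)
    if not has_excitation:
        raise FitError("all episodes have zero drive; activation is unidentifiable")
    has_decay = any(
        np.any(d.value[np.argmax(d.value > 0):] == 0) for d, *_ in episodes
    )
    if not has_decay:
        warnings.warn(
            "episodes contain no relaxation phase; beta is unidentifiable",
            IdentifiabilityWarning,
        )

    lo = np.array([b[0] for b in _ACTIVATION_BOUNDS.values()])
    hi = np.array([b[1] for b in _ACTIVATION_BOUNDS.values()])

    def _is_isometric(length):
        if callable(length):
            return None
        L = np.asarray(length[1], dtype=float)
        return float(L[0]) if np.ptp(L) < 1e-9 else None

    iso_L = [_is_isometric(length) for _, length, *_ in episodes]

    def loss(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return 1e6 * (1.0 + float(np.sum(np.abs(theta))))
        tau, beta, a0, g = theta
        trial = params.replace(tau=float(tau), beta=float(beta), a0=float(a0), g=float(g))
        total, count = 0.0, 0
        for (drive, length, t_meas, f_meas), L in zip(episodes, iso_L):
            t0 = float(t_meas[0])
            try:
                if L is not None:
                    f_sim = simulator.simulate_isometric_force(
                        trial, drive, L, t_meas
                    )
                else:
                    # start from the trial's own pre-stimulation equilibrium
                    u0 = float(np.atleast_1d(drive.u_f(t0, trial.A))[0])
                    ap0 = u0 / (trial.beta + (1.0 - trial.beta) * u0)
                    l0 = float(np.interp(t0, np.asarray(length[0]), np.asarray(length[1])))
                    sim = simulator.simulate_episode(
                        trial,
                        drive,
                        length,
                        t_span=(t0, float(t_meas[-1])),
                        initial_state=simulator.MuscleState(ap0, l0 / trial.L_mto),
                        rtol=1e-5,
                        atol=1e-7,
                        reporting_rate=reporting_rate,
                    )
                    f_sim = np.interp(t_meas, sim.time, sim.force)
            except simulator.SimulationError:
                return 1e6
            total += float(np.sum((f_sim - f_meas) ** 2))
            count += t_meas.size
        return total / count

    # deterministic coarse presearch: the simplex alone stalls in local
    # minima of this 4-parameter landscape when started far from truth
    grid = [
        np.array([tau, beta, a0, g])
        for tau in (0.3, 0.6, 1.2, 2.4)
        for beta in (0.08, 0.15, 0.3, 0.6)
        for a0 in (0.5, 0.74)
        for g in (2.0, 4.0)
    ]
    x0 = np.asarray(x0, dtype=float)
    starts = [x0] + grid
    losses = [loss(t) for t in starts]
    best_start = starts[int(np.argmin(losses))]

    res = minimize(
        loss,
        best_start,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-10},
    )
    # one restart from the optimum re-inflates the simplex
    res2 = minimize(
        loss,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-12},
    )
    if res2.fun < res.fun:
        res = res2
    theta = np.clip(res.x, lo, hi)
    return FitResult(
        coefficients=theta,
        rss=float(res.fun),
        n_points=sum(t.size for *_, t, _f in episodes),
        converged=bool(res.success or res2.success),
        diagnostics={
            "nelder_mead_iterations": int(res.nit),
            "has_decay_phase": bool(has_decay),
            "presearch_best": [float(v) for v in best_start],
        },
    )
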
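"""Constitutive relationships of the I1/I3 Hill-type muscle model.

The model lumps the muscle into a contractile element (CE) in series with a
linear spring (SEE), both in parallel with a passive elastic element (PE).
All functions here are pure evaluations of the fitted curve families:

* force--frequency sigmoid mapping stimulation frequency to neural drive,
* cubic active length--tension multipliers (in total-length or CE-length
  coordinates),
* piecewise-exponential passive length--tension,
* piecewise-hyperbolic force--velocity and its double-exponential inverse,
* first-order activation dynamics with distinct excitation and relaxation
  time constants.

Forces are normalized by the peak active isometric force ``F_mto`` and
lengths/velocities by the optimal length ``L_mto``. Shortening velocities
are positive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HillModelParameters",
    "InvalidParameterError",
    "force_frequency_response",
    "active_length_tension",
    "passive_length_tension",
    "force_velocity",
    "inverse_force_velocity",
    "series_elastic_force",
    "activation_derivative",
    "activation_steady_state",
    "activation_output",
    "total_muscle_force",
    "load_parameters",
    "save_parameters",
    "best_median_parameters",
    "i2_reference_parameters",
]

_DATA_DIR = Path(__file__).parent / "data"


class InvalidParameterError(ValueError):
    """Raised when model coefficients violate their structural requirements."""


@dataclass
class HillModelParameters:
    """Complete parameter set of the Hill-type muscle model.

    Attributes
    ----------
    F_mto : float
        Peak active isometric force, N.
    L_mto : float
        Optimal muscle length (length of peak active force), mm.
    L_0 : float
        Rest length of the muscle, mm.
    L_st : float
        Slack length of the series elastic element, mm (unknown in this
        muscle; fixed at 0).
    K_t : float
        Normalized series-elastic stiffness, F_mto per L_mto.
    A : ndarray, shape (4,)
        Force--frequency sigmoid coefficients; A[2] in 1/Hz, A[3] in Hz.
    B : ndarray, shape (4,)
        Active length--tension cubic in normalized total length l_mt.
    Y : ndarray, shape (4,)
        Active length--tension cubic in normalized CE length l_m.
    C : ndarray, shape (4,)
        Passive length--tension exponential coefficients.
    l_pe_threshold : float
        Normalized length below which passive force is zero.
    D : ndarray, shape (4,)
        Piecewise-hyperbola force--velocity coefficients.
    E : ndarray, shape (5,)
        Double-exponential inverse force--velocity coefficients.
    tau : float
        Activation time constant at full drive, s.
    beta : float
        Relaxation ratio; the relaxation time constant is tau/beta.
    a0 : float
        Activation offset subtracted before gain scaling.
    g : float
        Activation gain.
    """

    F_mto: float
    L_mto: float
    L_0: float
    K_t: float
    A: np.ndarray
    B: np.ndarray
    Y: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    tau: float
    beta: float
    a0: float
    g: float
    L_st: float = 0.0
    l_pe_threshold: float = 0.87

    def __post_init__(self) -> None:
        for name in ("A", "B", "Y", "C", "D", "E"):
            vec = np.asarray(getattr(self, name), dtype=float)
            want = 5 if name == "E" else 4
            if vec.shape != (want,):
                raise InvalidParameterError(
                    f"{name} must have {want} coefficients, got shape {vec.shape}"
                )
            if not np.all(np.isfinite(vec)):
                raise InvalidParameterError(f"{name} contains non-finite values")
            object.__setattr__(self, name, vec)
        for name in ("F_mto", "L_mto", "K_t", "tau", "g"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0 < self.beta <= 1:
            raise InvalidParameterError("beta must lie in (0, 1]")
        if self.D[1] <= 0 or self.D[3] <= 0:
            raise InvalidParameterError(
                "force-velocity poles D2 and D4 must be positive"
            )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("A", "B", "Y", "C", "D", "E"):
            out[key] = list(map(float, out[key]))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "HillModelParameters":
        return cls(**d)

    def replace(self, **changes) -> "HillModelParameters":
        return dataclasses.replace(self, **changes)


def _as_coeffs(vec, n: int, name: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (n,):
        raise InvalidParameterError(f"{name} must have {n} entries")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} contains non-finite values")
    return arr


def force_frequency_response(f_stim, A):
    """Neural drive u_f in [0, 1] from the stimulation frequency in Hz.

    Sigmoid ``A1 / (A1 + A2 * exp(-A3 * (f - A4)))``; with positive A1..A3
    it rises monotonically and saturates at 1.
    """
    A = _as_coeffs(A, 4, "A")
    f = np.asarray(f_stim, dtype=float)
    u = A[0] / (A[0] + A[1] * np.exp(-A[2] * (f - A[3])))
    return u if u.ndim else float(u)


def active_length_tension(l_norm, coeffs):
    """Raw cubic length--tension multiplier c1*l^3 + c2*l^2 + c3*l + c4.

    Used with the ``B`` vector (argument: normalized total length) or the
    ``Y`` vector (argument: normalized CE length). No clamping is applied
    here; the simulator floors negative values.
    """
    c = _as_coeffs(coeffs, 4, "LT coefficients")
    return np.polyval(c, np.asarray(l_norm, dtype=float))


def passive_length_tension(l_mt_norm, C, threshold: float = 0.87):
    """Normalized passive force of the parallel elastic element.

    Zero below ``threshold``; otherwise ``max(0, C1 + C2*exp(C3*l - C4))``.
    The clamp keeps the exponential branch from going slightly tensile just
    above the threshold (raw value about -0.0065 at 0.87 with the shipped
    coefficients, below measurement noise).
    """
    C = _as_coeffs(C, 4, "C")
    l = np.asarray(l_mt_norm, dtype=float)
    branch = C[0] + C[1] * np.exp(C[2] * l - C[3])
    out = np.where(l < threshold, 0.0, np.maximum(branch, 0.0))
    return out if out.ndim else float(out)


def force_velocity(v_m_norm, D):
    """Force--velocity multiplier for a normalized CE velocity.

    Shortening (v >= 0): ``1 + D1 / (1 + D2/v)``, dropping from 1 toward
    1 + D1 at high speed. Lengthening (v < 0): ``1 + D3 / (1 - D4/v)``,
    rising from 1 toward 1 + D3. Continuous at v = 0 with value 1.
    """
    D = _as_coeffs(D, 4, "D")
    if D[1] <= 0 or D[3] <= 0:
        raise InvalidParameterError("D2 and D4 must be positive")
    v = np.asarray(v_m_norm, dtype=float)
    with np.errstate(divide="ignore"):
        shortening = 1.0 + D[0] / (1.0 + D[1] / v)
        lengthening = 1.0 + D[2] / (1.0 - D[3] / v)
    out = np.where(v >= 0, shortening, lengthening)
    out = np.where(v == 0, 1.0, out)
    return out if out.ndim else float(out)


def inverse_force_velocity(fv_ratio, E):
    """Normalized CE velocity from a force--velocity ratio.

    Double exponential ``-E1*exp(E2*(FV - E3)) + E4*exp(E5*FV)``; with the
    fitted coefficient signs it decreases monotonically, crossing zero near
    FV = 1 (isometric) and approaching the maximum unloaded shortening
    velocity (about E4) as FV -> 0.
    """
    E = _as_coeffs(E, 5, "E")
    fv = np.asarray(fv_ratio, dtype=float)
    v = -E[0] * np.exp(E[1] * (fv - E[2])) + E[3] * np.exp(E[4] * fv)
    return v if v.ndim else float(v)


def series_elastic_force(l_t_norm, K_t: float):
    """Normalized SEE force K_t * l_t for a linear spring with zero slack."""
    if K_t <= 0:
        raise InvalidParameterError("K_t must be positive")
    out = K_t * np.asarray(l_t_norm, dtype=float)
    return out if out.ndim else float(out)


def activation_derivative(a_prime, u_f, tau: float, beta: float):
    """Time derivative of the pre-scaling activation a'.

    ``da'/dt = (u_f - [beta + (1-beta)*u_f] * a') / tau``. The effective
    time constant interpolates between tau at full drive and tau/beta with
    no drive, making relaxation slower than excitation.
    """
    if tau <= 0:
        raise InvalidParameterError("tau must be positive")
    if not 0 < beta <= 1:
        raise InvalidParameterError("beta must lie in (0, 1]")
    u = np.asarray(u_f, dtype=float)
    a = np.asarray(a_prime, dtype=float)
    out = (u - (beta + (1.0 - beta) * u) * a) / tau
    return out if out.ndim else float(out)


def activation_steady_state(u_f, beta: float):
    """Fixed point of the activation ODE: u_f / (beta + (1-beta)*u_f)."""
    u = np.asarray(u_f, dtype=float)
    out = u / (beta + (1.0 - beta) * u)
    return out if out.ndim else float(out)


def isometric_steady_activation(params: "HillModelParameters", f_stim):
    """Steady-state activation under constant stimulation frequency.

    Composes the drive sigmoid, the activation ODE fixed point and the
    gain/threshold output map. This — not the sigmoid alone — is the
    force--frequency relation an isometric experiment measures on this
    model: the threshold a0 silences low frequencies and the gain g
    steepens the rise.
    """
    u = force_frequency_response(f_stim, params.A)
    return activation_output(
        activation_steady_state(u, params.beta), params.g, params.a0
    )


def activation_output(a_prime, g: float, a0: float):
    """Scaled, thresholded activation a = clip(g*(a' - a0), 0, 1)."""
    if g <= 0:
        raise InvalidParameterError("g must be positive")
    out = np.clip(g * (np.asarray(a_prime, dtype=float) - a0), 0.0, 1.0)
    return out if out.ndim else float(out)


def total_muscle_force(
    params: HillModelParameters, l_mt_norm, l_m_norm, a=None
) -> float:
    """Total muscle force in N at a given geometric state.

    Passive force depends on total length; the CE force is transmitted
    through the SEE, so at mechanical equilibrium the active contribution
    equals the spring force ``K_t * (l_mt - l_m)``.
    """
    f_pe = passive_length_tension(l_mt_norm, params.C, params.l_pe_threshold)
    f_see = series_elastic_force(
        np.asarray(l_mt_norm, dtype=float) - np.asarray(l_m_norm, dtype=float),
        params.K_t,
    )
    return params.F_mto * (f_pe + f_see)


# -- parameter file I/O -------------------------------------------------------

def load_parameters(path) -> HillModelParameters:
    """Read a parameter JSON file (keys named after the dataclass fields)."""
    with open(path) as fh:
        return HillModelParameters.from_dict(json.load(fh))


def save_parameters(params: HillModelParameters, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


def best_median_parameters() -> HillModelParameters:
    """The shipped I1/I3 model: best-median individual fits per family."""
    return load_parameters(_DATA_DIR / "i1i3_best_median.json")


def i2_reference_parameters() -> dict:
    """Published I2 protractor-muscle reference values used in comparisons."""
    with open(_DATA_DIR / "i2_reference.json") as fh:
        return json.load(fh)
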
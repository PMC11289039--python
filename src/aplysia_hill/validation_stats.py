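"""EMG-driven validation and cohort summary statistics.

The validation stage turns a raw EMG recording into a neural-drive
surrogate: rectify, normalize by the maximum, take the upper envelope
through local peaks (minimum peak separation in samples), then find the
scalar frequency scaling that minimizes the mean squared error between the
simulated and measured force. Cohort parameters are summarized as
mean +/- sample standard deviation and compared against published
reference values with one-sample two-sided t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.optimize import minimize_scalar

from .model_core import HillModelParameters
from .simulator import DriveSignal, simulate_episode

__all__ = [
    "EnvelopeResult",
    "CohortSummary",
    "emg_envelope",
    "fit_emg_scale",
    "one_sample_t_test",
    "summarize_cohort",
    "alignment_shift",
]


@dataclass
class EnvelopeResult:
    """Rectified-EMG upper envelope, normalized to unit peak."""

    time: np.ndarray
    envelope: np.ndarray
    scale: float = 1.0
    shift_s: float = 0.0


@dataclass
class CohortSummary:
    """Mean, sample sd and one-sample t-test against a reference value."""

    mean: float
    sd: float
    n: int
    reference: float
    t: float
    p: float


def emg_envelope(
    time, signal, min_separation_samples: int = 1000
) -> EnvelopeResult:
    """Upper envelope of a rectified, max-normalized EMG signal.

    Local peaks of the rectified signal separated by at least
    ``min_separation_samples`` are linearly interpolated; the first and
    last samples anchor the interpolation. The default separation of 1000
    samples corresponds to 0.2 s at the rig's 5 kHz rate (the parameter is
    kept in samples, so other rates need rescaling by the caller).
    """
    time = np.asarray(time, dtype=float)
    x = np.abs(np.asarray(signal, dtype=float))
    if x.size <= 2 * min_separation_samples:
        raise ValueError(
            f"signal length {x.size} must exceed twice the minimum peak "
            f"separation ({min_separation_samples})"
        )
    peak = x.max()
    if peak == 0:
        warnings.warn("all-zero EMG signal; envelope is zero", UserWarning)
        return EnvelopeResult(time=time, envelope=np.zeros_like(x))
    x = x / peak
    idx, _ = sps.find_peaks(x, distance=min_separation_samples)
    anchors = np.unique(np.concatenate([[0], idx, [x.size - 1]]))
    env = np.interp(np.arange(x.size), anchors, x[anchors])
    env = np.maximum(env, 0.0)
    return EnvelopeResult(time=time, envelope=env)


def alignment_shift(time, reference, other, max_shift_s: Optional[float] = None) -> float:
    """Time by which ``other`` must be advanced to best align with ``reference``.

    Plain cross-correlation of the non-negative traces (no demeaning: both
    are transient force-like pulses, and subtracting the mean biases the
    peak toward zero lag on finite records). The shift is reported
    explicitly, never applied silently.
    """
    time = np.asarray(time, dtype=float)
    a = np.asarray(reference, dtype=float)
    b = np.asarray(other, dtype=float)
    dt = float(time[1] - time[0])
    corr = sps.correlate(a, b, mode="full")
    lags = sps.correlation_lags(a.size, b.size, mode="full")
    if max_shift_s is not None:
        keep = np.abs(lags * dt) <= max_shift_s
        corr, lags = corr[keep], lags[keep]
    return float(-lags[np.argmax(corr)] * dt)


def fit_emg_scale(
    params: HillModelParameters,
    envelope: EnvelopeResult,
    length_trajectory,
    measured_time,
    measured_force,
    scale_bounds: tuple[float, float] = (1.0, 200.0),
    reporting_rate: float = 100.0,
) -> dict:
    """Scalar EMG-to-frequency scaling minimizing simulated-force MSE.

    The scaled envelope is fed as the stimulation-frequency input of the
    model (through the force--frequency sigmoid); a bounded 1-D search
    finds the scale. Returns scale, simulated force on the measured time
    base, and the MSE at the optimum.
    """
    t_meas = np.asarray(measured_time, dtype=float)
    f_meas = np.asarray(measured_force, dtype=float)
    if np.max(envelope.envelope) <= 0:
        warnings.warn("zero envelope: scale is unidentifiable", UserWarning)
        return {"scale": np.nan, "mse": np.nan, "degenerate": True}

    def mse_for(scale: float) -> tuple[float, np.ndarray]:
        drive = DriveSignal(envelope.time, scale * envelope.envelope, mode="frequency")
        sim = simulate_episode(
            params,
            drive,
            length_trajectory,
            t_span=(float(t_meas[0]), float(t_meas[-1])),
            reporting_rate=reporting_rate,
        )
        f_sim = np.interp(t_meas, sim.time, sim.force)
        return float(np.mean((f_sim - f_meas) ** 2)), f_sim

    res = minimize_scalar(
        lambda s: mse_for(s)[0], bounds=scale_bounds, method="bounded",
        options={"xatol": 1e-2},
    )
    mse, f_sim = mse_for(float(res.x))
    if not np.isfinite(mse):
        raise RuntimeError("non-finite MSE in EMG scale search")
    return {
        "scale": float(res.x),
        "mse": mse,
        "simulated_force": f_sim,
        "degenerate": False,
    }


def one_sample_t_test(mean: float, sd: float, n: int, mu0: float) -> tuple[float, float]:
    """Two-sided one-sample t-test from summary statistics.

    t = (mean - mu0) / (sd / sqrt(n)), with n - 1 degrees of freedom.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("degenerate test: sd must be positive")
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def summarize_cohort(values, reference: float) -> CohortSummary:
    """Sample mean/sd (n-1 denominator) plus the t-test against a reference."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    t, p = one_sample_t_test(mean, sd, v.size, reference)
    return CohortSummary(mean=mean, sd=sd, n=int(v.size), reference=reference, t=t, p=p)
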
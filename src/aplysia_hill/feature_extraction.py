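"""Windowed feature extraction from servomotor episode traces.

Each characterization protocol (force--frequency, length--tension,
force--velocity) produces annotated traces of time, imposed length,
measured force and stimulation frequency. The extractors below reduce
them to characterization points using fixed averaging windows anchored to
the declared episode metadata — stimulation onset/offset and ramp times —
never to features hunted elsewhere in the trace.

Window conventions:

* force--frequency baseline: mean force over [onset - 20 s, onset - 5 s];
  active force: mean of baseline-subtracted force over a 2 s window
  centered on the in-stimulation peak;
* length--tension passive: mean force over [onset - 10 s, onset - 2 s];
  active: 1 s window centered on the in-stimulation peak, minus passive;
* force--velocity ramp endpoints: 1 ms window (ceil(fs/1000) samples)
  centered on the endpoint sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import active_length_tension

__all__ = [
    "EpisodeTrace",
    "FFPoint",
    "LTPoint",
    "FVPoint",
    "StiffnessRegressionPoint",
    "WindowError",
    "ProtocolError",
    "extract_ff_point",
    "normalize_ff_series",
    "extract_lt_point",
    "normalize_lt_series",
    "extract_fv_point",
    "active_force_rise_slope",
    "estimate_series_stiffness",
    "read_episode_csv",
    "write_episode_csv",
]


class WindowError(ValueError):
    """An averaging window does not fit inside the available data."""


class ProtocolError(ValueError):
    """Episode metadata is inconsistent with the requested extraction."""


@dataclass
class EpisodeTrace:
    """One annotated episode: uniformly sampled trace plus protocol metadata.

    ``protocol`` is one of ``"force_frequency"``, ``"length_tension"``,
    ``"force_velocity_passive"``, ``"force_velocity_active"``. Ramp times
    (``t_ramp_start``/``t_ramp_end``) and the lab-frame ramp velocity
    ``V_mt`` (mm/s, lengthening positive) apply to ramped protocols;
    stimulation times apply wherever the muscle is stimulated.
    """

    time: np.ndarray
    length: np.ndarray   # L_mt, mm
    force: np.ndarray    # N
    stim_freq: np.ndarray  # Hz, 0 when off
    protocol: str
    stim_onset: Optional[float] = None
    stim_offset: Optional[float] = None
    t_ramp_start: Optional[float] = None
    t_ramp_end: Optional[float] = None
    V_mt: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time", "length", "force", "stim_freq"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.time.shape == self.length.shape == self.force.shape == self.stim_freq.shape):
            raise ValueError("trace arrays must have identical shapes")
        dt = np.diff(self.time)
        if self.time.size < 2 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")
        dt0 = float(np.median(dt))
        if np.max(np.abs(dt - dt0)) > dt0 * 0.01:
            raise ValueError("time must be uniformly sampled")
        if self.stim_onset is not None and self.stim_offset is not None:
            if not self.stim_onset < self.stim_offset:
                raise ValueError("stim onset must precede offset")

    @property
    def fs(self) -> float:
        """Sampling rate, Hz."""
        return 1.0 / float(self.time[1] - self.time[0])

    def _window_mean(self, t_lo: float, t_hi: float, what: str) -> float:
        mask = (self.time >= t_lo) & (self.time <= t_hi)
        if not mask.any():
            raise WindowError(
                f"{what} window [{t_lo:.3f}, {t_hi:.3f}] s contains no samples "
                f"(trace spans [{self.time[0]:.3f}, {self.time[-1]:.3f}] s)"
            )
        return float(self.force[mask].mean())


@dataclass
class FFPoint:
    """Force--frequency characterization point (one isometric episode)."""

    f_stim: float
    active_force: float          # F_CE,e, N
    u_f: Optional[float] = None  # filled by normalize_ff_series


@dataclass
class LTPoint:
    """Length--tension characterization point (one isometric episode)."""

    l_mt: float                    # absolute length at stimulation, mm
    active_force: float            # F_CE,e, N
    passive_force: float           # F_PE,e, N
    l_mt_norm: Optional[float] = None
    lt_active: Optional[float] = None   # normalized active force
    f_pe_norm: Optional[float] = None


@dataclass
class FVPoint:
    """Force--velocity characterization point (one passive/active pair)."""

    v_m_norm: float        # normalized CE velocity, shortening positive
    fv_ratio: float
    V_mt: float            # lab-frame ramp velocity, mm/s
    F_iso_est_max: float   # corrected isometric force, N


@dataclass
class StiffnessRegressionPoint:
    """One (ramp velocity, active-force slope) sample for the K_t regression."""

    V_mt: float        # mm/s, lab frame
    dF_dt: float       # dF_CE/dt at the ramp end, N/s
    G: np.ndarray      # quartic coefficients of the F_CE(t) fit


# -- force-frequency ----------------------------------------------------------

def extract_ff_point(
    episode: EpisodeTrace,
    baseline_window: tuple[float, float] = (20.0, 5.0),
    peak_window_s: float = 2.0,
) -> FFPoint:
    """Active force of one isometric force--frequency episode.

    The baseline passive force is the mean over [onset - 20 s, onset - 5 s];
    the active force is the baseline-subtracted force averaged over a 2 s
    window centered on its in-stimulation peak (truncated at the
    stimulation bounds when the peak sits near an edge).
    """
    if episode.stim_onset is None or episode.stim_offset is None:
        raise ProtocolError("force-frequency episode needs stimulation times")
    on, off = episode.stim_onset, episode.stim_offset
    pre = on - episode.time[0]
    if pre < baseline_window[0] - 1e-9:
        raise WindowError(
            f"need {baseline_window[0]:.0f} s of pre-stimulation data, have {pre:.1f} s"
        )
    baseline = episode._window_mean(on - baseline_window[0], on - baseline_window[1], "baseline")

    stim_mask = (episode.time >= on) & (episode.time <= off)
    f_ce = episode.force[stim_mask] - baseline
    t_stim = episode.time[stim_mask]
    t_peak = float(t_stim[np.argmax(f_ce)])
    half = peak_window_s / 2.0
    w = (t_stim >= max(t_peak - half, on)) & (t_stim <= min(t_peak + half, off))
    freq = float(episode.stim_freq[stim_mask].max())
    return FFPoint(f_stim=freq, active_force=float(f_ce[w].mean()))


def normalize_ff_series(points: Sequence[FFPoint]) -> list[FFPoint]:
    """Normalize active forces by the per-muscle maximum (maps to 1)."""
    points = list(points)
    if not points:
        raise ValueError("no points to normalize")
    f_max = max(p.active_force for p in points)
    if f_max <= 0:
        raise ValueError("degenerate normalization: no positive active force")
    return [
        FFPoint(p.f_stim, p.active_force, u_f=p.active_force / f_max)
        for p in points
    ]


# -- length-tension -----------------------------------------------------------

def extract_lt_point(
    episode: EpisodeTrace,
    passive_window: tuple[float, float] = (10.0, 2.0),
    peak_window_s: float = 1.0,
) -> LTPoint:
    """Passive and active force of one isometric length--tension episode.

    Passive force: mean over [onset - 10 s, onset - 2 s] (the late
    pre-stimulation plateau, after passive transients have decayed).
    Active force: 1 s window centered on the in-stimulation peak, minus
    passive. Normalized fields are filled by :func:`normalize_lt_series`.
    """
    if episode.stim_onset is None or episode.stim_offset is None:
        raise ProtocolError("length-tension episode needs stimulation times")
    on, off = episode.stim_onset, episode.stim_offset
    passive = episode._window_mean(on - passive_window[0], on - passive_window[1], "passive")

    stim_mask = (episode.time >= on) & (episode.time <= off)
    if not stim_mask.any():
        raise ProtocolError("stimulation window lies outside the trace")
    t_stim = episode.time[stim_mask]
    f_stimwin = episode.force[stim_mask]
    t_peak = float(t_stim[np.argmax(f_stimwin)])
    half = peak_window_s / 2.0
    w = (t_stim >= max(t_peak - half, on)) & (t_stim <= min(t_peak + half, off))
    active = float(f_stimwin[w].mean()) - passive
    l_at_stim = float(np.interp(on, episode.time, episode.length))
    return LTPoint(l_mt=l_at_stim, active_force=active, passive_force=passive)


def normalize_lt_series(points: Sequence[LTPoint]) -> tuple[list[LTPoint], float, float]:
    """Second pass: per-muscle normalization of a length--tension series.

    The episode with the largest active force defines the muscle's optimal
    length ``L_mto_e`` and peak force ``F_mto_e``; lengths are divided by
    the former and both force channels by the latter, so the peak point
    maps to (1, 1) exactly.

    Returns the normalized points plus (F_mto_e, L_mto_e).
    """
    points = list(points)
    if not points:
        raise ValueError("no points to normalize")
    best = max(points, key=lambda p: p.active_force)
    F_mto_e, L_mto_e = best.active_force, best.l_mt
    if F_mto_e <= 0 or L_mto_e <= 0:
        raise ValueError("degenerate normalization: non-positive peak force or length")
    out = []
    for p in points:
        out.append(
            LTPoint(
                l_mt=p.l_mt,
                active_force=p.active_force,
                passive_force=p.passive_force,
                l_mt_norm=p.l_mt / L_mto_e,
                lt_active=p.active_force / F_mto_e,
                f_pe_norm=p.passive_force / F_mto_e,
            )
        )
    return out, F_mto_e, L_mto_e


# -- force-velocity -----------------------------------------------------------

def _endpoint_mean(episode: EpisodeTrace, t: float, window_s: float = 1e-3) -> float:
    """Mean force over the closed sample window centered at time t."""
    n = math.ceil(episode.fs * window_s)
    idx = int(round((t - float(episode.time[0])) * episode.fs))
    idx = int(np.clip(idx, 0, episode.time.size - 1))
    half = n // 2
    lo = max(idx - half, 0)
    hi = min(idx + half + 1, episode.time.size)
    return float(episode.force[lo:hi].mean())


def _passive_force_by_length(
    passive: EpisodeTrace, lengths: np.ndarray
) -> np.ndarray:
    """Passive ramp force looked up by muscle length, not by time.

    The passive ramp traverses the same lengths as the active ramp but at a
    different wall-clock time; matching by length aligns the two. Linear
    interpolation between bracketing samples of the passive ramp.
    """
    if passive.t_ramp_start is None or passive.t_ramp_end is None:
        raise ProtocolError("passive episode needs ramp times")
    mask = (passive.time >= passive.t_ramp_start) & (passive.time <= passive.t_ramp_end)
    l_ramp = passive.length[mask]
    f_ramp = passive.force[mask]
    order = np.argsort(l_ramp, kind="stable")
    return np.interp(lengths, l_ramp[order], f_ramp[order])


def active_force_rise_slope(
    active: EpisodeTrace,
    passive: EpisodeTrace,
    eval_time: Optional[float] = None,
    window_s: Optional[float] = None,
) -> tuple[float, np.ndarray]:
    """Slope of the active force rise during an isokinetic ramp.

    The CE force over the active ramp is the measured force minus the
    passive-ramp force at the matching *length*. A quartic in time is
    least-squares fitted to it and differentiated analytically at
    ``eval_time`` (default: the ramp end).

    ``window_s`` restricts the fit to samples within that distance of
    ``eval_time`` (still inside the ramp). The force transient during a
    ramp steepens as the series spring unloads, and a single quartic over
    a long ramp cannot track both phases; a window around the evaluation
    time keeps the endpoint derivative faithful.

    Returns (dF_CE/dt in N/s, quartic coefficients highest power first).
    """
    if active.t_ramp_start is None or active.t_ramp_end is None:
        raise ProtocolError("active episode needs ramp times")
    if eval_time is None:
        eval_time = float(active.t_ramp_end)
    mask = (active.time >= active.t_ramp_start) & (active.time <= active.t_ramp_end)
    if window_s is not None:
        mask &= (active.time >= eval_time - window_s) & (
            active.time <= eval_time + window_s
        )
    if mask.sum() < 5:
        raise WindowError(
            f"quartic fit needs >= 5 ramp samples, got {int(mask.sum())}"
        )
    t = active.time[mask]
    f_ce = active.force[mask] - _passive_force_by_length(passive, active.length[mask])
    # center time for conditioning; derivative is shift-invariant
    t0 = t.mean()
    G = np.polyfit(t - t0, f_ce, 4)
    slope = float(np.polyval(np.polyder(G), eval_time - t0))
    return slope, G


def _iso_capacity_at_ce_length(l_m_norm: float, B, K_t: float) -> float:
    """Isometric capacity read at a CE length, via the B fit and K_t.

    The B cubic maps total length to normalized isometric force; at
    isometric equilibrium the CE sits at l_m = l_mt - B(l_mt)/K_t. Given
    a CE length, invert that map for the total length whose isometric
    state puts the CE there, and return the capacity B at it. Falls back
    to the raw polynomial value if the inversion fails (far outside the
    fitted range).
    """
    from scipy.optimize import brentq

    g = lambda l: l - float(active_length_tension(l, B)) / K_t - l_m_norm
    lo, hi = l_m_norm, l_m_norm + 1.5 / K_t
    try:
        if g(lo) * g(hi) > 0:
            raise ValueError
        l_star = brentq(g, lo, hi, xtol=1e-10)
        return float(active_length_tension(l_star, B))
    except ValueError:
        return float(active_length_tension(l_m_norm, B))


def extract_fv_point(
    active: EpisodeTrace,
    passive: EpisodeTrace,
    B,
    K_t: float,
    L_mto: float,
    a: float = 1.0,
    capacity_at_ce_length: bool = True,
) -> FVPoint:
    """One force--velocity point from a matched passive/active episode pair.

    The FV ratio divides the end-of-ramp active force by the
    length-corrected isometric capacity:

    * active force = F_mt(t_a,end) - F_PE(t_p,end), 1 ms endpoint windows;
    * isometric capacity = F_iso_est_max * LT(l_mt at ramp end), where
      F_iso_est_max is the pre-ramp isometric force corrected by the LT fit
      at the ramp-start length;
    * CE velocity = ramp velocity minus the SEE absorption term
      (dF_CE/dt) / (K_t_dimensional), converted to the shortening-positive
      normalized convention.

    ``a`` defaults to 1 (stimulation at a saturating frequency).

    With ``capacity_at_ce_length`` (default), the length--tension
    multiplier in the denominator is evaluated at the series-elasticity-
    corrected CE length rather than the total length: right after a ramp
    the CE force differs from its isometric value at that length, so the
    CE sits at a different length than the isometric fit assumes. The
    isometric-capacity curve is re-expressed in CE coordinates through
    the fitted B cubic and the stiffness (the same shift that produces
    the Y fit) and read at the measured CE length. Disable to reproduce
    the plain total-length evaluation.
    """
    if active.V_mt is None or passive.V_mt is None:
        raise ProtocolError("episodes need ramp velocities")
    if abs(active.V_mt - passive.V_mt) > 1e-9:
        raise ProtocolError(
            f"passive ramp velocity {passive.V_mt} does not match active {active.V_mt}"
        )
    for ep, kind in ((active, "active"), (passive, "passive")):
        if ep.t_ramp_start is None or ep.t_ramp_end is None:
            raise ProtocolError(f"{kind} episode needs ramp times")

    F_mt_end = _endpoint_mean(active, float(active.t_ramp_end))
    F_pe_end = _endpoint_mean(passive, float(passive.t_ramp_end))
    F_mt_start = _endpoint_mean(active, float(active.t_ramp_start))
    F_pe_start = _endpoint_mean(passive, float(passive.t_ramp_start))

    l_start_norm = float(np.interp(active.t_ramp_start, active.time, active.length)) / L_mto
    l_end_norm = float(np.interp(active.t_ramp_end, active.time, active.length)) / L_mto
    lt_start = float(active_length_tension(l_start_norm, B))
    if lt_start <= 0:
        raise ProtocolError(f"LT fit non-positive at ramp start (l={l_start_norm:.3f})")
    F_iso_est_max = (F_mt_start - F_pe_start) / lt_start

    F_ce_end = F_mt_end - F_pe_end
    if capacity_at_ce_length:
        lt_end = _iso_capacity_at_ce_length(
            l_end_norm - (F_ce_end / F_iso_est_max) / K_t, B, K_t
        )
    else:
        lt_end = float(active_length_tension(l_end_norm, B))
    denom = F_iso_est_max * a * lt_end
    if denom <= 0:
        raise ProtocolError("degenerate FV denominator (a * LT <= 0)")
    fv_ratio = F_ce_end / denom

    ramp_dur = float(active.t_ramp_end - active.t_ramp_start)
    w = min(ramp_dur, max(0.5 * ramp_dur, 0.1))
    slope, _G = active_force_rise_slope(active, passive, window_s=w)
    # lab frame (lengthening positive): the SEE absorbs dF_CE/dt / K_t of
    # the imposed velocity; forces scale by the episode's own isometric
    # estimate (robust to electrode movement between episodes)
    vm_lab = active.V_mt / L_mto - slope / (K_t * F_iso_est_max)
    # shortening-positive convention for the model curves
    return FVPoint(
        v_m_norm=-vm_lab,
        fv_ratio=float(fv_ratio),
        V_mt=float(active.V_mt),
        F_iso_est_max=float(F_iso_est_max),
    )


def estimate_series_stiffness(
    points: Sequence[StiffnessRegressionPoint],
    F_mto: float,
    L_mto: float,
) -> tuple[float, dict]:
    """Series-elastic stiffness from the dF_CE/dt vs ramp-velocity line.

    During an isokinetic ramp the SEE absorbs the difference between the
    imposed and CE velocities, so the active-force slope is proportional to
    the ramp velocity with proportionality K_t (the CE velocity term is
    neglected, as in the regression this estimate mirrors). Ordinary least
    squares across ramp velocities; the slope, scaled by L_mto/F_mto,
    is the dimensionless stiffness. The intercept is reported as a
    diagnostic, not constrained to zero.
    """
    points = list(points)
    v = np.array([p.V_mt for p in points], dtype=float)
    dfdt = np.array([p.dF_dt for p in points], dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct ramp velocities")
    slope, intercept = np.polyfit(v, dfdt, 1)
    K_t = float(slope * L_mto / F_mto)
    resid = dfdt - (slope * v + intercept)
    return K_t, {
        "slope_N_per_mm": float(slope),
        "intercept_N_per_s": float(intercept),
        "rss": float(np.sum(resid**2)),
        "n": len(points),
    }


# -- episode CSV + sidecar I/O ------------------------------------------------

_CSV_COLUMNS = ["time_s", "length_mm", "force_N", "stim_hz"]


def write_episode_csv(episode: EpisodeTrace, csv_path, meta_path=None) -> None:
    """Write an episode as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "time_s": episode.time,
            "length_mm": episode.length,
            "force_N": episode.force,
            "stim_hz": episode.stim_freq,
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "protocol": episode.protocol,
        "stim_onset": episode.stim_onset,
        "stim_offset": episode.stim_offset,
        "t_ramp_start": episode.t_ramp_start,
        "t_ramp_end": episode.t_ramp_end,
        "V_mt": episode.V_mt,
        **episode.meta,
    }
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def read_episode_csv(csv_path, meta_path=None) -> EpisodeTrace:
    """Read an episode CSV and its metadata sidecar, validating both."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing columns {missing}")
    for col in _CSV_COLUMNS:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{csv_path}: non-finite {col} at line {bad[0] + 2}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    known = {"protocol", "stim_onset", "stim_offset", "t_ramp_start", "t_ramp_end", "V_mt"}
    return EpisodeTrace(
        time=df["time_s"].to_numpy(),
        length=df["length_mm"].to_numpy(),
        force=df["force_N"].to_numpy(),
        stim_freq=df["stim_hz"].to_numpy(),
        protocol=meta.get("protocol", "unknown"),
        stim_onset=meta.get("stim_onset"),
        stim_offset=meta.get("stim_offset"),
        t_ramp_start=meta.get("t_ramp_start"),
        t_ramp_end=meta.get("t_ramp_end"),
        V_mt=meta.get("V_mt"),
        meta={k: v for k, v in meta.items() if k not in known},
    )
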
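"""Synthetic servomotor experiments from a known ground-truth model.

No recordings were deposited with the characterization study this package
reimplements, so every pipeline stage is exercised against episodes
synthesized by running the forward model through the original rig
protocols:

* force--frequency: isometric 5 s trains at 2--38 Hz in 6 Hz steps;
* length--tension: 20 s ramps stepping the length from rest through
  -1 mm to +8 mm offsets, stimulation (>= 26 Hz, 5 s) 110 s after each
  ramp; the first two episodes are conditioning and tagged as such;
* force--velocity: paired passive/active +-0.5 mm isokinetic ramps around
  rest length at +-{0.25, 0.5, 1, 2, 4, 8} mm/s, with a 5 s isometric
  stimulation hold before the active ramp.

The rig sampled at 5 kHz with 180 s rests between episodes. Synthesis
defaults to a 500 Hz "desk-scale" rate and compresses the rests: the model
is memoryless between episodes once activation has decayed, so rests are
realized as state resets rather than integrated wall time. Pre-stimulation
plateaus are kept long enough for every extraction window.

An EMG-like validation input is synthesized as a burst-envelope-modulated
noise carrier with the ground-truth envelope returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .feature_extraction import EpisodeTrace
from .model_core import HillModelParameters, passive_length_tension
from .simulator import DriveSignal, simulate_episode

__all__ = [
    "ProtocolSpec",
    "NoiseSpec",
    "ProtocolEpisode",
    "generate_protocol",
    "synthesize_episode",
    "synthesize_protocol",
    "synthesize_emg_drive",
]

FF_FREQUENCIES_HZ = (2.0, 8.0, 14.0, 20.0, 26.0, 32.0, 38.0)
LT_OFFSETS_MM = (0.0, -1.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
FV_SPEEDS_MM_S = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class ProtocolSpec:
    """Timing and sampling of one characterization protocol.

    ``kind`` is one of ``"force_frequency"``, ``"length_tension"``,
    ``"force_velocity"``. Defaults reproduce the rig protocols at
    desk-scale sampling; ``pre_stim_s`` sets how much settled
    pre-stimulation trace each episode carries (must cover the widest
    extraction window).
    """

    kind: str
    fs: float = 500.0
    stim_freq: float = 26.0          # Hz used for LT/FV stimulation
    stim_duration_s: float = 5.0
    pre_stim_s: float = 25.0
    post_stim_s: float = 20.0
    frequencies: Sequence[float] = FF_FREQUENCIES_HZ
    lt_offsets_mm: Sequence[float] = LT_OFFSETS_MM
    lt_ramp_s: float = 20.0
    fv_speeds_mm_s: Sequence[float] = FV_SPEEDS_MM_S
    fv_half_excursion_mm: float = 0.5
    fv_iso_hold_s: float = 5.0       # stimulation before the active ramp

    def __post_init__(self) -> None:
        if self.kind not in ("force_frequency", "length_tension", "force_velocity"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.fs <= 0 or self.stim_duration_s <= 0 or self.pre_stim_s <= 0:
            raise ValueError("durations and sampling rate must be positive")
        if self.kind == "force_velocity" and not self.fv_speeds_mm_s:
            raise ValueError("velocity set must be nonempty")


@dataclass
class NoiseSpec:
    """Additive measurement noise on the force channel.

    ``passive_transient_N`` optionally adds a stretched-exponential
    stress-relaxation transient after each length ramp (the real muscle
    shows transients up to ~0.35 N; the model deliberately excludes them),
    for extractor robustness tests only.
    """

    force_sd_N: float = 0.0
    seed: Optional[int] = None
    passive_transient_N: float = 0.0
    passive_transient_tau_s: float = 30.0

    def __post_init__(self) -> None:
        if self.force_sd_N < 0:
            raise ValueError("noise sd must be >= 0")
        if self.force_sd_N > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise is enabled")
        if not 0 <= self.passive_transient_N <= 0.35:
            raise ValueError("passive transient amplitude must be in [0, 0.35] N")


@dataclass
class ProtocolEpisode:
    """One episode's inputs: length trajectory, stimulation, metadata.

    ``length`` is a (time, L_mt mm) sample pair; ``stim`` a (time, Hz)
    step schedule (held between samples). Metadata mirrors what the
    feature extractors require.
    """

    protocol: str
    length_time: np.ndarray
    length_mm: np.ndarray
    stim_time: np.ndarray
    stim_hz: np.ndarray
    duration_s: float
    stim_onset: Optional[float] = None
    stim_offset: Optional[float] = None
    t_ramp_start: Optional[float] = None
    t_ramp_end: Optional[float] = None
    V_mt: Optional[float] = None
    start_length_mm: Optional[float] = None
    meta: dict = field(default_factory=dict)


def generate_protocol(
    spec: ProtocolSpec, params: HillModelParameters
) -> list[ProtocolEpisode]:
    """Expand a protocol spec into per-episode length/stimulation schedules."""
    L0 = params.L_0
    if spec.kind == "force_frequency":
        return [_ff_episode(spec, L0, f) for f in spec.frequencies]
    if spec.kind == "length_tension":
        eps = []
        prev = L0
        for i, off in enumerate(spec.lt_offsets_mm):
            eps.append(_lt_episode(spec, L0, prev, L0 + off, conditioning=i < 2))
            prev = L0 + off
        return eps
    episodes = []
    for speed in spec.fv_speeds_mm_s:          # shortening trials first
        episodes.extend(_fv_pair(spec, L0, -abs(speed)))
    for speed in spec.fv_speeds_mm_s:
        episodes.extend(_fv_pair(spec, L0, abs(speed)))
    return episodes


def _ff_episode(spec: ProtocolSpec, L0: float, freq: float) -> ProtocolEpisode:
    on = spec.pre_stim_s
    off = on + spec.stim_duration_s
    dur = off + spec.post_stim_s
    return ProtocolEpisode(
        protocol="force_frequency",
        length_time=np.array([0.0, dur]),
        length_mm=np.array([L0, L0]),
        stim_time=np.array([0.0, on, off]),
        stim_hz=np.array([0.0, freq, 0.0]),
        duration_s=dur,
        stim_onset=on,
        stim_offset=off,
        start_length_mm=L0,
        meta={"f_stim": freq},
    )


def _lt_episode(
    spec: ProtocolSpec, L0: float, L_from: float, L_to: float, conditioning: bool
) -> ProtocolEpisode:
    """Ramp from the previous length to the target, rest, then stimulate.

    The real protocol stimulates 110 s after the ramp; here the rest is
    compressed to ``pre_stim_s`` because the model's passive force settles
    as soon as the CE length equilibrates (no stress-relaxation state).
    """
    ramp_end = spec.lt_ramp_s
    on = ramp_end + spec.pre_stim_s
    off = on + spec.stim_duration_s
    dur = off + spec.post_stim_s
    return ProtocolEpisode(
        protocol="length_tension",
        length_time=np.array([0.0, ramp_end, dur]),
        length_mm=np.array([L_from, L_to, L_to]),
        stim_time=np.array([0.0, on, off]),
        stim_hz=np.array([0.0, spec.stim_freq, 0.0]),
        duration_s=dur,
        stim_onset=on,
        stim_offset=off,
        t_ramp_start=0.0,
        t_ramp_end=ramp_end,
        V_mt=(L_to - L_from) / spec.lt_ramp_s,
        start_length_mm=L_from,
        meta={"conditioning": conditioning, "offset_mm": L_to - L0},
    )


def _fv_pair(
    spec: ProtocolSpec, L0: float, V_mt: float
) -> list[ProtocolEpisode]:
    """Matched passive and active isokinetic episodes at one velocity.

    Lengthening (V_mt > 0) runs L0-0.5 -> L0+0.5 mm; shortening the
    reverse. The active episode holds an isometric stimulation for
    ``fv_iso_hold_s`` before the ramp and keeps stimulating through it.
    """
    h = spec.fv_half_excursion_mm
    start = L0 - h if V_mt > 0 else L0 + h
    end = L0 + h if V_mt > 0 else L0 - h
    ramp_dur = abs(end - start) / abs(V_mt)

    settle = 5.0  # passive settle before the ramp
    p_ramp_start = settle
    p_ramp_end = settle + ramp_dur
    p_dur = p_ramp_end + 5.0
    passive = ProtocolEpisode(
        protocol="force_velocity_passive",
        length_time=np.array([0.0, p_ramp_start, p_ramp_end, p_dur]),
        length_mm=np.array([start, start, end, end]),
        stim_time=np.array([0.0]),
        stim_hz=np.array([0.0]),
        duration_s=p_dur,
        t_ramp_start=p_ramp_start,
        t_ramp_end=p_ramp_end,
        V_mt=V_mt,
        start_length_mm=start,
    )

    on = 2.0
    a_ramp_start = on + spec.fv_iso_hold_s
    a_ramp_end = a_ramp_start + ramp_dur
    off = on + 10.0 if on + 10.0 > a_ramp_end else a_ramp_end + 1.0
    a_dur = off + 5.0
    active = ProtocolEpisode(
        protocol="force_velocity_active",
        length_time=np.array([0.0, a_ramp_start, a_ramp_end, a_dur]),
        length_mm=np.array([start, start, end, end]),
        stim_time=np.array([0.0, on, off]),
        stim_hz=np.array([0.0, spec.stim_freq, 0.0]),
        duration_s=a_dur,
        stim_onset=on,
        stim_offset=off,
        t_ramp_start=a_ramp_start,
        t_ramp_end=a_ramp_end,
        V_mt=V_mt,
        start_length_mm=start,
    )
    return [passive, active]


def synthesize_episode(
    params: HillModelParameters,
    episode: ProtocolEpisode,
    noise: Optional[NoiseSpec] = None,
    fs: float = 500.0,
) -> EpisodeTrace:
    """Run the forward model over one protocol episode and sample it.

    Unstimulated episodes are evaluated analytically: with zero
    activation the CE transmits no force, the series spring stays slack,
    and the muscle force is purely the passive curve of the imposed
    length. Stimulated episodes are integrated with the ODE simulator.
    Identical inputs and seed give bit-identical traces.
    """
    noise = noise or NoiseSpec()
    n = int(round(episode.duration_s * fs))
    t = np.arange(n + 1) / fs

    length = np.interp(t, episode.length_time, episode.length_mm)
    if np.all(episode.stim_hz == 0):
        f_pe = np.asarray(
            passive_length_tension(length / params.L_mto, params.C, params.l_pe_threshold)
        )
        force = params.F_mto * f_pe
    else:
        drive = DriveSignal(
            np.asarray(episode.stim_time, dtype=float),
            np.asarray(episode.stim_hz, dtype=float),
            mode="frequency",
        )
        result = simulate_episode(
            params,
            drive,
            (episode.length_time, episode.length_mm),
            t_span=(0.0, float(t[-1])),
            reporting_rate=fs,
        )
        force = np.interp(t, result.time, result.force)

    if noise.passive_transient_N > 0 and episode.t_ramp_end is not None:
        after = t >= episode.t_ramp_end
        force = force + np.where(
            after,
            noise.passive_transient_N
            * np.exp(-np.sqrt(np.maximum(t - episode.t_ramp_end, 0.0) / noise.passive_transient_tau_s)),
            0.0,
        )
    if noise.force_sd_N > 0:
        rng = np.random.default_rng(noise.seed)
        force = force + rng.normal(0.0, noise.force_sd_N, size=force.shape)

    stim = np.zeros_like(t)
    for t_k, f_k in zip(episode.stim_time, episode.stim_hz):
        stim[t >= t_k] = f_k
    return EpisodeTrace(
        time=t,
        length=length,
        force=force,
        stim_freq=stim,
        protocol=episode.protocol,
        stim_onset=episode.stim_onset,
        stim_offset=episode.stim_offset,
        t_ramp_start=episode.t_ramp_start,
        t_ramp_end=episode.t_ramp_end,
        V_mt=episode.V_mt,
        meta=dict(episode.meta),
    )


def synthesize_protocol(
    params: HillModelParameters,
    spec: ProtocolSpec,
    noise: Optional[NoiseSpec] = None,
) -> list[EpisodeTrace]:
    """Generate and synthesize every episode of a protocol.

    With noise enabled, each episode gets an independent substream of the
    seed so traces are reproducible episode-by-episode.
    """
    noise = noise or NoiseSpec()
    episodes = generate_protocol(spec, params)
    traces = []
    for k, ep in enumerate(episodes):
        ep_noise = noise
        if noise.force_sd_N > 0:
            ep_noise = replace(noise, seed=noise.seed + 1000 * k)
        traces.append(synthesize_episode(params, ep, ep_noise, fs=spec.fs))
    return traces


def synthesize_emg_drive(
    duration_s: float = 20.0,
    fs: float = 1000.0,
    burst_start_s: float = 4.0,
    burst_duration_s: float = 6.0,
    carrier_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EMG-like burst: envelope-modulated noise carrier.

    The envelope rises as a smooth half-cosine ramp into a plateau and
    back down, emulating a rectified-EMG burst during nerve stimulation.
    Returns (time, signal, true_envelope); the raw signal is zero-mean
    noise scaled by the envelope, the ground truth against which envelope
    recovery is tested.
    """
    if burst_duration_s <= 0:
        raise ValueError("burst duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    env = np.zeros_like(t)
    ramp = min(1.0, burst_duration_s / 4.0)
    t0, t1 = burst_start_s, burst_start_s + burst_duration_s
    rising = (t >= t0) & (t < t0 + ramp)
    plateau = (t >= t0 + ramp) & (t < t1 - ramp)
    falling = (t >= t1 - ramp) & (t < t1)
    env[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - t0) / ramp))
    env[plateau] = 1.0
    env[falling] = 0.5 * (1 - np.cos(np.pi * (t1 - t[falling]) / ramp))
    signal = env * rng.normal(0.0, carrier_sd, size=t.shape)
    return t, signal, env
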
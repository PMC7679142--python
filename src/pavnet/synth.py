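"""Synthetic session generator for a two-valence Pavlovian conditioning task.

Emulates multi-region recordings (anterior/posterior insular cortex and three
central-amygdala populations) across the four learning stages of a combined
reward/fear paradigm: per-neuron event trains with CS/US-locked rate
modulation, directed lag coupling between populations, LFP with phase-locked
oscillatory components riding on 1/f noise, calcium traces built from event
trains, a motion-index trace, and a behavioral timeline whose correctness is
configurable.  Every downstream analysis stage is tested against the structure
planted here.

Event generation is discretized at 1 s bins (the analysis resolution); a
uniform sub-bin jitter is added so that 500 ms binning remains meaningful.
Coupling acts on the per-bin event *probability* (Bernoulli), keeping states
binary for information-theoretic analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

REGIONS = ("aIC", "pIC", "CE_SST", "CE_PKCd", "CEm")
STAGES = ("habituation", "C_early", "C_late", "recall")
CS_DURATION = 10.0  # s, fixed stimulus length

__all__ = [
    "REGIONS",
    "STAGES",
    "CS_DURATION",
    "SynthConfig",
    "EventTrain",
    "SessionTimeline",
    "LFPRecord",
    "CalciumTrace",
    "MotionTrace",
    "generate_session",
    "generate_coupled_pair",
    "generate_calcium",
]


class SchedulingError(ValueError):
    """Trial schedule does not fit in the session."""


@dataclass(frozen=True)
class Coupling:
    """Directed lag coupling: a source-region event at bin t raises the
    paired target neuron's event probability by ``excess_prob`` at bin
    t + ``lag_bins``."""

    source: str
    target: str
    excess_prob: float
    lag_bins: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.excess_prob <= 1.0:
            raise ValueError(f"excess_prob must be in [0,1], got {self.excess_prob}")
        if self.lag_bins < 1:
            raise ValueError("lag_bins must be >= 1")


@dataclass(frozen=True)
class Oscillation:
    """LFP oscillatory component with optional spike phase locking
    (von Mises concentration ``locking_kappa``; 0 = no locking)."""

    region: str
    freq: float
    amplitude: float
    locking_kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.locking_kappa < 0:
            raise ValueError("locking_kappa must be >= 0")
        if self.freq <= 0:
            raise ValueError("freq must be > 0")


@dataclass
class SynthConfig:
    """Full parameterization of one synthetic session.

    ``cs_response_amp`` / ``us_response_amp`` map ``(region, stimulus_type,
    stage)`` to a rate multiplier applied inside the CS window / for
    ``us_response_bins`` bins after the US.  Unlisted combinations default
    to 1 (no modulation).
    """

    n_neurons_per_region: dict[str, int] = field(
        default_factory=lambda: {"aIC": 40, "pIC": 40, "CE_SST": 20, "CE_PKCd": 20, "CEm": 15}
    )
    baseline_rate: dict[str, float] = field(
        default_factory=lambda: {r: 0.2 for r in REGIONS}
    )
    cs_response_amp: dict[tuple[str, str, str], float] = field(default_factory=dict)
    us_response_amp: dict[tuple[str, str, str], float] = field(default_factory=dict)
    coupling: list[Coupling] = field(default_factory=list)
    lfp_osc: list[Oscillation] = field(default_factory=list)
    behavior_correct_prob: float = 0.8
    session_length: float = 600.0
    n_trials_per_cs: int = 6
    stage: str = "recall"
    treatment: str = "control"
    us_response_bins: int = 3
    lfp_fs: float = 1000.0
    motion_fs: float = 20.0
    freezing_duration: float = 3.0  # s, length of planted freezing bouts
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.behavior_correct_prob <= 1.0:
            raise ValueError("behavior_correct_prob must be in [0,1]")
        for r, rate in self.baseline_rate.items():
            if rate < 0:
                raise ValueError(f"negative baseline rate for {r}")
        for c in self.coupling:
            if c.source not in self.n_neurons_per_region or c.target not in self.n_neurons_per_region:
                raise ValueError(f"coupling references unknown region: {c}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EventTrain:
    """Per-neuron event timestamps (spikes or calcium events), seconds."""

    neuron_id: str
    region: str
    stage: str
    event_times: np.ndarray
    treatment: str = "control"

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        t = np.unique(t)  # sorted, deduplicated
        self.event_times = t

    @property
    def n_events(self) -> int:
        return len(self.event_times)


@dataclass
class SessionTimeline:
    """CS trials, US deliveries and behavioral episode onsets for a session.

    CS trials are (onset_s, cs_type) with the fixed 10 s duration; USs are
    (time_s, us_type); behavior episodes are (onset_s, kind) with kind in
    {"port_visit", "freezing_onset"}.
    """

    cs_trials: list[tuple[float, str]] = field(default_factory=list)
    us_events: list[tuple[float, str]] = field(default_factory=list)
    behavior_episodes: list[tuple[float, str]] = field(default_factory=list)
    session_length: float = 600.0
    cs_duration: float = CS_DURATION

    def __post_init__(self) -> None:
        self.cs_trials = sorted(self.cs_trials)
        self.us_events = sorted(self.us_events)
        self.behavior_episodes = sorted(self.behavior_episodes)

    def cs_windows(self, cs_type: str | None = None) -> list[tuple[float, float, str]]:
        return [
            (on, on + self.cs_duration, typ)
            for on, typ in self.cs_trials
            if cs_type is None or typ == cs_type
        ]


@dataclass
class LFPRecord:
    region: str
    samples: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class CalciumTrace:
    """Raw fluorescence, baseline and relative change dF/F = (F - F0)/F0."""

    dff: np.ndarray
    fs: float = 20.0
    raw: np.ndarray | None = None
    f0: float | None = None
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.raw is not None and self.f0 is not None:
            recon = (np.asarray(self.raw) - self.f0) / self.f0
            if not np.allclose(recon, self.dff, atol=1e-9):
                raise ValueError("dff inconsistent with raw and f0")

    def times(self) -> np.ndarray:
        return np.arange(len(self.dff)) / self.fs


@dataclass
class MotionTrace:
    motion: np.ndarray
    fs: float = 20.0

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        if len(self.motion) == 0:
            raise ValueError("empty motion trace")
        finite = self.motion[np.isfinite(self.motion)]
        if finite.size and finite.min() < 0:
            raise ValueError("motion index must be nonnegative")


# ---------------------------------------------------------------------------
# schedule


def _make_schedule(cfg: SynthConfig, rng: np.random.Generator) -> SessionTimeline:
    """Lay out non-overlapping CS trials (alternating blocks of two, as in the
    behavioral design) with USs at CS offset during conditioning stages."""
    n_total = 2 * cfg.n_trials_per_cs
    # each trial occupies CS (10 s) + >= 20 s inter-trial interval
    slot = cfg.session_length / n_total
    if slot < CS_DURATION + 20.0:
        raise SchedulingError(
            f"{n_total} trials do not fit in {cfg.session_length} s "
            f"(need >= {n_total * (CS_DURATION + 20.0):.0f} s)"
        )
    # blocks of two per CS type: R R F F R R F F ...
    order: list[str] = []
    types = ["R", "F"]
    for i in range(n_total // 2):
        order.extend([types[i % 2]] * 2)
    order = order[:n_total]
    cs_trials = []
    us_events = []
    for i, typ in enumerate(order):
        lo = i * slot + 10.0
        hi = (i + 1) * slot - CS_DURATION - 8.0
        onset = float(rng.uniform(lo, min(hi, lo + 5.0)))
        cs_trials.append((onset, typ))
        if cfg.stage in ("C_early", "C_late"):
            # US of type X only follows CS of type X
            us_events.append((onset + CS_DURATION, typ))
    return SessionTimeline(
        cs_trials=cs_trials,
        us_events=us_events,
        session_length=cfg.session_length,
    )


def _place_behavior(
    cfg: SynthConfig, timeline: SessionTimeline, rng: np.random.Generator
) -> list[tuple[float, str]]:
    """One episode per CS trial: correct (inside the matching CS) with
    probability behavior_correct_prob, else placed in an inter-trial interval
    at least 5 s from any CS window."""
    kinds = {"R": "port_visit", "F": "freezing_onset"}
    episodes: list[tuple[float, str]] = []
    windows = [(on - 5.0, on + CS_DURATION + 5.0) for on, _ in timeline.cs_trials]

    def outside_cs(t: float) -> bool:
        return all(not (lo <= t < hi) for lo, hi in windows)

    for onset, typ in timeline.cs_trials:
        kind = kinds[typ]
        if rng.random() < cfg.behavior_correct_prob:
            episodes.append((onset + float(rng.uniform(0.5, CS_DURATION - 1.0)), kind))
        else:
            for _ in range(200):
                t = float(rng.uniform(5.0, cfg.session_length - 10.0))
                if outside_cs(t):
                    episodes.append((t, kind))
                    break
    return episodes


# ---------------------------------------------------------------------------
# event trains


def _bin_rate_profile(
    cfg: SynthConfig, region: str, timeline: SessionTimeline, n_bins: int
) -> np.ndarray:
    """Per-1 s-bin event probability for one region, before coupling."""
    base = cfg.baseline_rate.get(region, 0.0)  # events/s == per-bin prob scale
    p = np.full(n_bins, base, dtype=float)
    for onset, typ in timeline.cs_trials:
        amp = cfg.cs_response_amp.get((region, typ, cfg.stage), 1.0)
        b0, b1 = int(onset), int(onset + CS_DURATION)
        p[b0:b1] = base * amp
    for t_us, typ in timeline.us_events:
        amp = cfg.us_response_amp.get((region, typ, cfg.stage), 1.0)
        b0 = int(t_us)
        p[b0 : b0 + cfg.us_response_bins] = base * amp
    return np.clip(p, 0.0, 1.0)


def _draw_region_states(
    cfg: SynthConfig,
    timeline: SessionTimeline,
    n_bins: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Binary (neuron x bin) state arrays per region, honoring coupling.

    Regions are processed in dependency order (sources before targets);
    cyclic coupling is rejected.  Each target neuron is paired round-robin
    with one source neuron so the planted lag is visible pairwise.
    """
    targets = {c.target for c in cfg.coupling}
    order = [r for r in cfg.n_neurons_per_region if r not in targets]
    remaining = [r for r in cfg.n_neurons_per_region if r in targets]
    for _ in range(len(remaining) + 1):
        for r in list(remaining):
            deps = {c.source for c in cfg.coupling if c.target == r}
            if deps.issubset(order):
                order.append(r)
                remaining.remove(r)
    if remaining:
        raise ValueError(f"cyclic coupling involving {remaining}")

    states: dict[str, np.ndarray] = {}
    for region in order:
        n = cfg.n_neurons_per_region[region]
        p = _bin_rate_profile(cfg, region, timeline, n_bins)  # (n_bins,)
        prob = np.tile(p, (n, 1))
        for c in cfg.coupling:
            if c.target != region:
                continue
            src = states[c.source]
            n_src = src.shape[0]
            for i in range(n):
                x = src[i % n_src]
                boost = np.zeros(n_bins)
                boost[c.lag_bins :] = x[: n_bins - c.lag_bins] * c.excess_prob
                prob[i] = np.clip(prob[i] + boost, 0.0, 1.0)
        states[region] = (rng.random((n, n_bins)) < prob).astype(np.int8)
    return states


def _lfp_for_region(
    cfg: SynthConfig, region: str, n_samples: int, rng: np.random.Generator
) -> LFPRecord:
    """1/f (pink) noise plus the configured sinusoidal components."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / cfg.lfp_fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    pink = np.fft.irfft(spec * shaping, n=n_samples)
    pink *= 1.0 / max(pink.std(), 1e-12)
    t = np.arange(n_samples) / cfg.lfp_fs
    for osc in cfg.lfp_osc:
        if osc.region == region:
            phase0 = float(rng.uniform(0, 2 * np.pi))
            pink = pink + osc.amplitude * np.sin(2 * np.pi * osc.freq * t + phase0)
    return LFPRecord(region=region, samples=pink * 50.0, fs=cfg.lfp_fs)


def _jitter_events(
    states: np.ndarray,
    region: str,
    cfg: SynthConfig,
    lfp: LFPRecord | None,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Place each binary bin event at a sub-bin time.

    Unlocked neurons get uniform jitter.  If the region has an oscillation
    with locking_kappa > 0, spike phase relative to that component is drawn
    from a von Mises density (kappa=0 reduces to uniform)."""
    lock = next(
        (o for o in cfg.lfp_osc if o.region == region and o.locking_kappa > 0), None
    )
    out = []
    for row in states:
        bins = np.flatnonzero(row).astype(float)
        if lock is None:
            times = bins + rng.uniform(0.0, 1.0, size=len(bins))
        else:
            # draw a phase, pick a random cycle inside the bin
            theta = rng.vonmises(0.0, lock.locking_kappa, size=len(bins))
            frac = (theta % (2 * np.pi)) / (2 * np.pi)
            n_cycles = max(int(lock.freq), 1)
            cyc = rng.integers(0, n_cycles, size=len(bins))
            times = bins + (cyc + frac) / lock.freq
            times = np.minimum(times, bins + 0.999)
        out.append(np.sort(times))
    return out


def _motion_trace(
    cfg: SynthConfig, timeline: SessionTimeline, rng: np.random.Generator
) -> MotionTrace:
    """High baseline motion; near-zero during planted freezing bouts."""
    n = int(cfg.session_length * cfg.motion_fs)
    motion = np.abs(rng.normal(5.0, 1.0, size=n))
    motion = np.maximum(motion, 1.0)  # keep baseline clearly above thresholds
    for onset, kind in timeline.behavior_episodes:
        if kind != "freezing_onset":
            continue
        i0 = int(onset * cfg.motion_fs)
        i1 = min(int((onset + cfg.freezing_duration) * cfg.motion_fs), n)
        motion[i0:i1] = np.abs(rng.normal(0.02, 0.005, size=i1 - i0))
    return MotionTrace(motion=motion, fs=cfg.motion_fs)


def generate_session(
    config: SynthConfig,
) -> tuple[
    list[EventTrain],
    SessionTimeline,
    dict[str, LFPRecord],
    list[CalciumTrace],
    MotionTrace,
]:
    """Generate one complete synthetic session, reproducible from the seed.

    Returns event trains for every neuron, the session timeline, one LFP
    record per region, calcium traces for the CE populations (built from
    their event trains), and a motion-index trace consistent with the
    planted freezing episodes.
    """
    rng = np.random.default_rng(config.seed)
    n_bins = int(config.session_length)
    timeline = _make_schedule(config, rng)
    timeline.behavior_episodes = _place_behavior(config, timeline, rng)

    states = _draw_region_states(config, timeline, n_bins, rng)
    n_samples = int(config.session_length * config.lfp_fs)
    lfps = {
        region: _lfp_for_region(config, region, n_samples, rng)
        for region in config.n_neurons_per_region
    }

    trains: list[EventTrain] = []
    for region in config.n_neurons_per_region:
        times_list = _jitter_events(states[region], region, config, lfps.get(region), rng)
        for i, times in enumerate(times_list):
            trains.append(
                EventTrain(
                    neuron_id=f"{region}_{i:03d}",
                    region=region,
                    stage=config.stage,
                    treatment=config.treatment,
                    event_times=times,
                )
            )

    calcium: list[CalciumTrace] = []
    for train in trains:
        if train.region.startswith("CE"):
            tr = generate_calcium(
                train,
                amp=1.0,
                tau_decay=0.5,
                noise_sd=0.02,
                fs=20.0,
                seed=int(rng.integers(0, 2**31 - 1)),
                duration=config.session_length,
            )
            tr.trace_id = train.neuron_id
            calcium.append(tr)

    motion = _motion_trace(config, timeline, rng)
    return trains, timeline, lfps, calcium, motion


def generate_coupled_pair(
    len_bins: int,
    p_base: float,
    excess_prob: float,
    lag: int = 1,
    seed: int = 0,
    p_base_y: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal binary source/target pair with lag-only dependence.

    X is iid Bernoulli(p_base).  Y fires at bin t with probability
    ``p_base_y + excess_prob`` if X fired at t - lag, else ``p_base_y``
    (``p_base_y`` defaults to ``p_base``).  The conditional excess
    probability therefore equals ``excess_prob`` exactly.
    """
    if not (0 <= p_base <= 1 and 0 <= excess_prob <= 1):
        raise ValueError("probabilities must be in [0,1]")
    if len_bins < lag + 2:
        raise ValueError("len_bins must be >= lag + 2")
    py = p_base if p_base_y is None else p_base_y
    rng = np.random.default_rng(seed)
    x = (rng.random(len_bins) < p_base).astype(np.int8)
    prob = np.full(len_bins, py)
    prob[lag:] = np.clip(py + x[:-lag] * excess_prob, 0.0, 1.0)
    y = (rng.random(len_bins) < prob).astype(np.int8)
    return x, y


def generate_calcium(
    events: EventTrain,
    amp: float,
    tau_decay: float,
    noise_sd: float,
    fs: float = 20.0,
    seed: int = 0,
    duration: float | None = None,
) -> CalciumTrace:
    """Convolve an event train with an exponential transient kernel.

    dff(t) = sum_k amp * exp(-(t - t_k)/tau_decay) for t >= t_k, plus
    Gaussian noise; raw F is reconstructed from a positive baseline F0.
    """
    if amp <= 0 or tau_decay <= 0:
        raise ValueError("amp and tau_decay must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if duration is None:
        duration = (events.event_times[-1] + 5 * tau_decay) if events.n_events else 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    dff = np.zeros(n)
    for t_ev in events.event_times:
        mask = t >= t_ev
        dff[mask] += amp * np.exp(-(t[mask] - t_ev) / tau_decay)
    if noise_sd > 0:
        dff = dff + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    f0 = 100.0
    raw = f0 * (1.0 + dff)
    return CalciumTrace(dff=dff, fs=fs, raw=raw, f0=f0, trace_id=events.neuron_id)
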
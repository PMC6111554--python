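"""Synthetic annotated stretch-sensor respiration recordings.

Real chest-band data for the talking-detection problem are not publicly
available, so this module generates recordings with the statistical
structure the detector assumes:

* **quiet breathing** — rhythmic cycles at a resting-adult rate of 12-18
  breaths/min with roughly balanced inhale and exhale phases;
* **speech breathing** — a fast inhalation (default ~0.55 s) followed by a
  long, slow exhalation (default ~4 s) with strongly jittered cycle timing
  and amplitude, the pattern produced when air is taken in quickly and
  released gradually while speaking.

Each breath cycle is a piecewise half-cosine: a rise from baseline to the
cycle amplitude over the inhale duration, then a fall back over the exhale
duration.  The half-cosine keeps the waveform band-limited while letting
the inhale/exhale asymmetry be dialled independently.

A full recording reproduces the laboratory block protocol — per trial, one
2-min non-talking block followed by one 2-min talking block, five trials
per activity — then applies per-channel gain, sinusoidal baseline drift,
Gaussian sensor noise and activity-dependent movement-artifact transients
to the resistance series, and finally pushes each channel through the
voltage-divider forward model so the output is in acquired volts, exactly
what the real DAQ would deliver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import (
    ACTIVITIES,
    CHANNEL_NAMES,
    DividerConfig,
    RawRecording,
)

__all__ = [
    "BreathMorphology",
    "SimulationConfig",
    "DividerConfig",
    "BreathTrain",
    "SimulationLog",
    "QUIET_PRESET",
    "SPEECH_PRESET",
    "simulate_breath_train",
    "simulate_recording",
    "resistance_to_voltage",
]


@dataclass(frozen=True)
class BreathMorphology:
    """Shape parameters of one class of breath cycle.

    ``rate_jitter`` is a coefficient of variation applied multiplicatively
    to per-cycle durations and amplitudes.
    """

    inhale_duration: float  # s
    exhale_duration: float  # s
    amplitude: float        # kOhm resistance excursion above baseline
    rate_jitter: float      # CV, dimensionless

    def __post_init__(self):
        if self.inhale_duration <= 0 or self.exhale_duration <= 0:
            raise ValueError("phase durations must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.rate_jitter < 0:
            raise ValueError("rate_jitter must be nonnegative")

    @property
    def cycle_duration(self) -> float:
        return self.inhale_duration + self.exhale_duration

    @property
    def rate_per_min(self) -> float:
        return 60.0 / self.cycle_duration


#: Resting breathing at 15 breaths/min (mid physiological 12-18 range),
#: near-balanced phases, low cycle-to-cycle variability.
QUIET_PRESET = BreathMorphology(
    inhale_duration=1.9, exhale_duration=2.1, amplitude=10.0, rate_jitter=0.05
)

#: Speech breathing: fast inhale, long controlled exhale (~13 breaths/min),
#: irregular timing and amplitude.
SPEECH_PRESET = BreathMorphology(
    inhale_duration=0.55, exhale_duration=4.0, amplitude=12.0, rate_jitter=0.25
)

# activity -> movement-artifact rate, events per minute
DEFAULT_ARTIFACT_RATES = {"sitting": 0.0, "standing": 2.0, "walking": 6.0}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    activity: str = "sitting"
    n_trials: int = 5
    block_duration: float = 120.0  # s per talk block and per non-talk block
    quiet: BreathMorphology = QUIET_PRESET
    speech: BreathMorphology = SPEECH_PRESET
    channel_gains: tuple[float, float, float] = (1.0, 0.8, 0.6)
    noise_sd: float = 0.1          # kOhm
    drift_amplitude: float = 2.0   # kOhm
    drift_period: float = 60.0     # s
    artifact_rate: float | None = None  # events/min; None -> activity default
    artifact_scale: float = 5.0    # kOhm, mean transient height
    artifact_tau: float = 0.8      # s, transient decay constant
    divider: DividerConfig = field(default_factory=DividerConfig)
    sample_rate: float = 100.0     # Hz

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.n_trials < 1 or self.block_duration <= 0:
            raise ValueError("n_trials >= 1 and block_duration > 0 required")
        if any(g <= 0 for g in self.channel_gains):
            raise ValueError("channel gains must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be nonnegative")
        fastest = 1.0 / min(self.quiet.inhale_duration, self.quiet.exhale_duration,
                            self.speech.inhale_duration, self.speech.exhale_duration)
        if self.sample_rate <= 2 * fastest:
            raise ValueError("sample_rate must exceed twice the fastest phase rate")

    @property
    def effective_artifact_rate(self) -> float:
        if self.artifact_rate is not None:
            return self.artifact_rate
        return DEFAULT_ARTIFACT_RATES[self.activity]


@dataclass
class CycleRecord:
    """One simulated breath cycle, as actually drawn (after jitter)."""

    start: float           # s, cycle onset
    inhale_duration: float
    exhale_duration: float
    amplitude: float
    kind: str              # "quiet" | "speech"

    @property
    def ratio(self) -> float:
        """Inhale/exhale duration ratio — short for speech, near 1 for quiet."""
        return self.inhale_duration / self.exhale_duration


@dataclass
class ArtifactRecord:
    time: float       # s
    height: float     # kOhm, signed
    channel: str


@dataclass
class BreathTrain:
    """Resistance-excursion series (kOhm above baseline) plus its cycle log."""

    series: np.ndarray
    sample_rate: float
    cycles: list[CycleRecord]


@dataclass
class SimulationLog:
    """Ground-truth internals of one simulated recording."""

    cycles: list[CycleRecord]
    artifacts: list[ArtifactRecord]


def _half_cosine_cycle(inhale_s: int, exhale_s: int, amplitude: float) -> np.ndarray:
    rise = amplitude * 0.5 * (1 - np.cos(np.pi * np.arange(inhale_s) / inhale_s))
    fall = amplitude * 0.5 * (1 + np.cos(np.pi * np.arange(exhale_s) / exhale_s))
    return np.concatenate([rise, fall])


def simulate_breath_train(
    kind: str,
    duration: float,
    morphology: BreathMorphology,
    rng: np.random.Generator,
    sample_rate: float = 100.0,
) -> BreathTrain:
    """Concatenate jittered breath cycles into a ``duration``-second series.

    Each cycle rises from 0 to its (jittered) amplitude over the inhale
    phase and falls back over the exhale phase.  The output has exactly
    ``round(duration * sample_rate)`` samples; the last cycle is truncated
    at the boundary.
    """
    if kind not in ("quiet", "speech"):
        raise ValueError(f"kind must be 'quiet' or 'speech', got {kind!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < morphology.cycle_duration:
        raise ValueError("duration shorter than one breath cycle")

    n_total = int(round(duration * sample_rate))
    out = np.zeros(n_total)
    cycles: list[CycleRecord] = []
    pos = 0
    while pos < n_total:
        jit = 1.0 + morphology.rate_jitter * rng.standard_normal(3)
        jit = np.clip(jit, 0.3, 3.0)  # keep phases physical under heavy jitter
        inhale = morphology.inhale_duration * jit[0]
        exhale = morphology.exhale_duration * jit[1]
        amp = morphology.amplitude * jit[2]
        n_in = max(2, int(round(inhale * sample_rate)))
        n_ex = max(2, int(round(exhale * sample_rate)))
        cycle = _half_cosine_cycle(n_in, n_ex, amp)
        end = min(pos + len(cycle), n_total)
        out[pos:end] = cycle[: end - pos]
        cycles.append(
            CycleRecord(
                start=pos / sample_rate,
                inhale_duration=n_in / sample_rate,
                exhale_duration=n_ex / sample_rate,
                amplitude=amp,
                kind=kind,
            )
        )
        pos += len(cycle)
    return BreathTrain(series=out, sample_rate=sample_rate, cycles=cycles)


def resistance_to_voltage(r: np.ndarray | float, divider: DividerConfig) -> np.ndarray | float:
    """Divider forward model: v = v_source * r / (r_reference + r).

    Monotone in r, bounded in [0, v_source) for finite r >= 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("resistance must be nonnegative")
    v = divider.v_source * r / (divider.r_reference + r)
    return v if v.ndim else float(v)


def _artifact_transients(
    n: int, sample_rate: float, rate_per_min: float, scale: float, tau: float,
    channel: str, rng: np.random.Generator,
) -> tuple[np.ndarray, list[ArtifactRecord]]:
    """Random-time, random-sign exponential-decay transients (movement noise)."""
    out = np.zeros(n)
    events: list[ArtifactRecord] = []
    duration_min = n / sample_rate / 60.0
    count = rng.poisson(rate_per_min * duration_min)
    times = np.sort(rng.uniform(0, n / sample_rate, size=count))
    for t in times:
        height = rng.choice([-1.0, 1.0]) * rng.exponential(scale)
        i0 = int(t * sample_rate)
        span = int(6 * tau * sample_rate)
        idx = np.arange(i0, min(i0 + span, n))
        out[idx] += height * np.exp(-(idx - i0) / (tau * sample_rate))
        events.append(ArtifactRecord(time=float(t), height=float(height), channel=channel))
    return out, events


def simulate_recording(config: SimulationConfig) -> RawRecording:
    """Simulate one participant-activity recording under the block protocol.

    For each of ``n_trials``: one non-talk block (quiet morphology) then
    one talk block (speech morphology).  The shared breath timing drives
    all three channels; gains, drift phase, noise and artifacts are drawn
    independently per channel.  The returned :class:`RawRecording` holds
    voltages; its ``simulation_log`` attribute holds the ground-truth cycle
    and artifact-event records (not serialized by ``write_recording``).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    block = config.block_duration

    pieces: list[np.ndarray] = []
    cycles: list[CycleRecord] = []
    talk_intervals: list[tuple[float, float]] = []
    t0 = 0.0
    for _ in range(config.n_trials):
        quiet = simulate_breath_train("quiet", block, config.quiet, rng, fs)
        speech = simulate_breath_train("speech", block, config.speech, rng, fs)
        for c in quiet.cycles:
            cycles.append(replace(c, start=c.start + t0))
        for c in speech.cycles:
            cycles.append(replace(c, start=c.start + t0 + block))
        pieces.extend([quiet.series, speech.series])
        talk_intervals.append((t0 + block, t0 + 2 * block))
        t0 += 2 * block

    excursion = np.concatenate(pieces)
    n = len(excursion)
    t = np.arange(n) / fs

    channels: dict[str, np.ndarray] = {}
    artifacts: list[ArtifactRecord] = []
    for name, gain in zip(CHANNEL_NAMES, config.channel_gains):
        drift_phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period + drift_phase
        )
        noise = config.noise_sd * rng.standard_normal(n)
        art, events = _artifact_transients(
            n, fs, config.effective_artifact_rate,
            config.artifact_scale, config.artifact_tau, name, rng,
        )
        artifacts.extend(events)
        r = config.divider.r_base + gain * excursion + drift + noise + art
        np.clip(r, 0.0, None, out=r)  # resistance is physical, cannot go negative
        channels[name] = resistance_to_voltage(r, config.divider)

    rec = RawRecording(
        participant_id="sim",
        activity=config.activity,
        sample_rate=fs,
        channels=channels,
        talk_intervals=talk_intervals,
        divider=config.divider,
    )
    rec.simulation_log = SimulationLog(cycles=cycles, artifacts=artifacts)
    return rec
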
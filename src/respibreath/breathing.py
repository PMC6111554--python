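"""Bandpass filtering, breath-peak detection and analysis-window extraction.

The resistance signal of each band is bandpass filtered with a 4th-order
Butterworth (0.1-1.5 Hz) to remove baseline drift and high-frequency
noise while keeping the physiological breathing band (resting adults
breathe 12-18 times/min, i.e. 0.2-0.3 Hz; the upper cutoff leaves room
for the fast inhalations of speech breathing).  The stated cutoffs are the
half-power (-3 dB) frequencies of a single filter pass; by default the
filter is applied forward and backward (zero net phase, attenuation
doubled) so detected peak times are not shifted relative to the talk
annotations.

Every inhalation expands the torso and produces a peak in the filtered
signal.  Peaks are selected by topographic prominence — the peak height
above the higher of the two lowest valleys separating it from any taller
sample — with an empirical minimum of 5 (kOhm, on the filtered resistance
signal).  A 3-s window centred on each retained peak is the unit that is
featurized and classified downstream; a window is labelled *talking* iff
its peak time falls inside an annotated talk interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_io import CHANNEL_NAMES, ResistanceRecording


@dataclass(frozen=True)
class FilterConfig:
    """Breathing-band Butterworth bandpass design."""

    order: int = 4
    low_cut: float = 0.1    # Hz, half-power point (single pass)
    high_cut: float = 1.5   # Hz
    zero_phase: bool = True

    def validate(self, sample_rate: float) -> None:
        if not (0 < self.low_cut < self.high_cut < sample_rate / 2):
            raise ValueError("require 0 < low_cut < high_cut < sample_rate/2")

    def sos(self, sample_rate: float) -> np.ndarray:
        self.validate(sample_rate)
        return signal.butter(
            self.order, [self.low_cut, self.high_cut],
            btype="bandpass", fs=sample_rate, output="sos",
        )


@dataclass(frozen=True)
class DetectorConfig:
    min_prominence: float = 5.0   # kOhm, on the filtered resistance signal
    window_length: float = 3.0    # s

    def __post_init__(self):
        if self.min_prominence <= 0 or self.window_length <= 0:
            raise ValueError("min_prominence and window_length must be positive")


@dataclass(frozen=True)
class BreathEvent:
    """One detected breath: a peak and its centred analysis window."""

    channel: str
    peak_index: int
    prominence: float
    window_start: int  # sample index, inclusive
    window_end: int    # sample index, exclusive
    label: int         # 1 = talking

    def peak_time(self, sample_rate: float) -> float:
        return self.peak_index / sample_rate


def bandpass(x: np.ndarray, cfg: FilterConfig, sample_rate: float) -> np.ndarray:
    """Apply the breathing bandpass; zero-phase (forward-backward) by default."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if len(x) <= 3 * cfg.order:
        raise ValueError(f"series too short to filter (need > {3 * cfg.order} samples)")
    sos = cfg.sos(sample_rate)
    if cfg.zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def prominence(x: np.ndarray, i: int) -> float:
    """Topographic prominence of the local maximum at index ``i``.

    Height of ``x[i]`` above the higher of the two minimal valleys found
    walking left and right until a taller sample (or the series end) is
    reached.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < i < len(x) - 1) or not (x[i - 1] <= x[i] >= x[i + 1]) or (
        x[i - 1] == x[i] == x[i + 1]
    ):
        raise ValueError(f"index {i} is not a local maximum")
    proms, _, _ = signal.peak_prominences(x, [i])
    return float(proms[0])


def detect_breaths(
    x: np.ndarray, cfg: DetectorConfig, sample_rate: float
) -> np.ndarray:
    """Indices of all local maxima with prominence >= ``min_prominence``.

    Plateau maxima are reduced to their leftmost sample; indices are
    returned in increasing order.  ``sample_rate`` is accepted for
    interface symmetry (the threshold is in signal units, not time).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    _, props = signal.find_peaks(
        x, prominence=cfg.min_prominence, plateau_size=(1, None)
    )
    return props["left_edges"].astype(int)


def extract_windows(
    peaks: np.ndarray,
    rec: ResistanceRecording,
    cfg: DetectorConfig,
    channel: str,
    prominences: np.ndarray | None = None,
) -> list[BreathEvent]:
    """Cut a ``window_length`` window centred on each peak and label it.

    A breath is *talking* (label 1) iff its peak time lies in a talk
    interval, half-open ``[start, end)``.  Peaks closer than half a window
    to either edge of the recording are dropped.
    """
    fs = rec.sample_rate
    half = int(round(cfg.window_length * fs / 2))
    n = rec.n_samples
    if prominences is None:
        prominences = np.full(len(peaks), np.nan)
    events: list[BreathEvent] = []
    for peak, prom in zip(np.asarray(peaks, dtype=int), prominences):
        start, end = peak - half, peak + half
        if start < 0 or end > n:
            continue  # edge peak: the centred window would leave the recording
        label = int(rec.is_talking(peak / fs))
        events.append(
            BreathEvent(
                channel=channel,
                peak_index=int(peak),
                prominence=float(prom),
                window_start=start,
                window_end=end,
                label=label,
            )
        )
    return events


def group_breath_events(
    events: list[BreathEvent], sample_rate: float, gap_s: float = 1.0
) -> np.ndarray:
    """Group ids assigning events of the same physical breath together.

    One inhalation expands the torso under all three bands, so the pooled
    event stream contains up to three near-simultaneous events per breath
    whose analysis windows overlap almost completely.  Events whose peak
    times are separated by less than ``gap_s`` (well below a breath cycle)
    are assigned the same group; cross-validation folds must respect these
    groups or near-duplicate windows leak across the train/test boundary.
    Expects events sorted by peak index (as ``detect_all`` returns them).
    """
    groups = np.zeros(len(events), dtype=int)
    gid = 0
    for k in range(1, len(events)):
        dt = (events[k].peak_index - events[k - 1].peak_index) / sample_rate
        if dt > gap_s:
            gid += 1
        groups[k] = gid
    return groups


def detect_all(
    rec: ResistanceRecording,
    filter_cfg: FilterConfig = FilterConfig(),
    detector_cfg: DetectorConfig = DetectorConfig(),
) -> list[BreathEvent]:
    """Filter every channel, detect its breaths and pool the events.

    The downstream event stream is the union across the three bands, each
    event tagged with its channel, ordered by peak time then channel name.
    """
    events: list[BreathEvent] = []
    for name in CHANNEL_NAMES:
        filtered = bandpass(rec.channels[name], filter_cfg, rec.sample_rate)
        peaks = detect_breaths(filtered, detector_cfg, rec.sample_rate)
        proms, _, _ = (
            signal.peak_prominences(filtered, peaks)
            if len(peaks)
            else (np.array([]), None, None)
        )
        events.extend(extract_windows(peaks, rec, detector_cfg, name, proms))
    events.sort(key=lambda e: (e.peak_index, e.channel))
    return events
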
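"""Linear (time-domain) contractile-physiology metrics.

A beating waveform shows two speed peaks per beat cycle: one for the
contraction stroke and one for the relaxation stroke. Peaks are detected by
prominence, grouped into beat cycles by their inter-peak gap structure, and
summarized as beat rate, peak-to-peak (PP) interval, and contraction /
relaxation velocities (mean ± sd).

PP intervals are measured contraction-peak to next contraction-peak; the
per-interval instantaneous rate 60/PP is averaged to give the beat rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .motiontrack import MotionWaveform

__all__ = ["Stat", "PeakSet", "BeatMetrics", "detect_peaks", "beat_metrics"]

CONTRACTION = "contraction"
RELAXATION = "relaxation"


@dataclass
class Stat:
    """Mean ± sample standard deviation (sd is NaN for singletons)."""

    mean: float
    sd: float
    n: int

    @staticmethod
    def of(values: np.ndarray) -> "Stat":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            return Stat(float("nan"), float("nan"), 0)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        return Stat(float(np.mean(v)), sd, int(v.size))

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n": self.n}


@dataclass
class PeakSet:
    """Labelled peak list: times (s), values (µm/s), labels, sample indices."""

    times: np.ndarray
    values: np.ndarray
    labels: list[str]
    indices: np.ndarray
    warning: str | None = None

    def select(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        mask = np.array([l == label for l in self.labels], dtype=bool)
        if mask.size == 0:
            return np.array([]), np.array([])
        return self.times[mask], self.values[mask]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class BeatMetrics:
    beat_rate_bpm: Stat
    pp_interval_s: Stat
    contraction_velocity_um_s: Stat
    relaxation_velocity_um_s: Stat
    peaks: PeakSet
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beat_rate_bpm": self.beat_rate_bpm.to_dict(),
            "pp_interval_s": self.pp_interval_s.to_dict(),
            "contraction_velocity_um_s": self.contraction_velocity_um_s.to_dict(),
            "relaxation_velocity_um_s": self.relaxation_velocity_um_s.to_dict(),
            "n_contraction_peaks": int(sum(l == CONTRACTION for l in self.peaks.labels)),
            "n_relaxation_peaks": int(sum(l == RELAXATION for l in self.peaks.labels)),
            "peak_times_s": [float(t) for t in self.peaks.times],
            "peak_labels": list(self.peaks.labels),
            "flags": list(self.flags),
        }


def _cycle_starts(times: np.ndarray) -> list[int]:
    """Indices that open a new beat cycle.

    Twin-peak beats produce alternating short (intra-beat) and long
    (inter-beat) gaps; the split point is the largest relative jump in the
    sorted gap sequence. When all gaps are comparable (single-peak beats)
    every peak opens its own cycle.
    """
    n = times.size
    if n <= 1:
        return [0] if n else []
    gaps = np.diff(times)
    sg = np.sort(gaps)
    if sg[0] <= 0 or sg[-1] / sg[0] <= 1.5:
        return list(range(n))  # unimodal gaps: one peak per cycle
    # first substantial jump separates intra-beat from inter-beat gaps
    # (later, larger jumps belong to missed beats and must stay inter-beat)
    ratios = sg[1:] / sg[:-1]
    split = int(np.argmax(ratios > 1.5))
    thr = float(np.sqrt(sg[split] * sg[split + 1]))  # geometric midpoint
    starts = [0]
    for i, g in enumerate(gaps):
        if g > thr:
            starts.append(i + 1)
    return starts


def detect_peaks(
    w: MotionWaveform,
    min_prominence_frac: float = 0.15,
    min_separation_s: float = 0.1,
    larger_is_contraction: bool = False,
) -> PeakSet:
    """Find speed peaks and label them contraction / relaxation.

    Local maxima with prominence >= ``min_prominence_frac`` of the signal
    range and pairwise separation >= ``min_separation_s`` are kept, then
    grouped into beat cycles. By default the first peak of each cycle is the
    contraction (contraction precedes relaxation within a beat); with
    ``larger_is_contraction`` the tallest peak of the cycle is used instead.

    A constant signal (or one without qualifying peaks) yields an empty
    result with ``warning`` set, not an exception.
    """
    if w.n < 3:
        raise ValueError("need at least 3 samples for peak detection")
    if not (0.0 < min_prominence_frac < 1.0):
        raise ValueError("min_prominence_frac must be in (0, 1)")
    S = w.S
    rng = float(S.max() - S.min())
    if rng == 0.0:
        return PeakSet(np.array([]), np.array([]), [], np.array([], dtype=int), "no_peaks")
    distance = max(1, int(round(min_separation_s * w.fps)))
    idx, _ = find_peaks(S, prominence=min_prominence_frac * rng, distance=distance)
    if idx.size == 0:
        return PeakSet(np.array([]), np.array([]), [], np.array([], dtype=int), "no_peaks")
    times, values = w.t[idx], S[idx]
    starts = _cycle_starts(times)
    bounds = starts + [len(idx)]
    labels = [RELAXATION] * len(idx)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if larger_is_contraction:
            c = a + int(np.argmax(values[a:b]))
        else:
            c = a
        labels[c] = CONTRACTION
    return PeakSet(times, values, labels, idx)


def beat_metrics(w: MotionWaveform, peaks: PeakSet) -> BeatMetrics:
    """Beat rate, PP interval, and stroke velocities from labelled peaks.

    With fewer than 2 contraction peaks the rate/PP statistics are undefined
    (NaN) and the result is flagged rather than raising, so batch pipelines
    survive dead samples.
    """
    flags: list[str] = []
    if peaks.warning:
        flags.append(peaks.warning)
    c_times, c_vals = peaks.select(CONTRACTION)
    r_times, r_vals = peaks.select(RELAXATION)
    if c_times.size >= 2:
        pp = np.diff(c_times)
        rate = Stat.of(60.0 / pp)
        pp_stat = Stat.of(pp)
    else:
        flags.append("insufficient_contraction_peaks")
        rate = Stat(float("nan"), float("nan"), 0)
        pp_stat = Stat(float("nan"), float("nan"), 0)
    return BeatMetrics(
        beat_rate_bpm=rate,
        pp_interval_s=pp_stat,
        contraction_velocity_um_s=Stat.of(c_vals),
        relaxation_velocity_um_s=Stat.of(r_vals),
        peaks=peaks,
        flags=flags,
    )
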
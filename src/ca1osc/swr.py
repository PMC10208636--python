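"""Sharp-wave-ripple, high-gamma, and HFO event detection.

Events are detected on the pyramidal-layer LFP by bandpass filtering
(ripple band 100-250 Hz; high gamma 80-120 Hz; HFO 110-160 Hz),
z-scoring and rectifying the filtered trace, smoothing with a secondary
1-20 Hz bandpass to obtain the envelope, and thresholding: candidate
events must exceed the amplitude threshold (3 SD for SWR, 1 SD for the
other bands), extend to the 1 SD crossings on either side, last at least
50 ms, and events closer than 125 ms are merged.  Candidates that are
concurrently detected on a distant "noise" channel are discarded as
non-biological artifacts (muscle/electrical noise appears on both,
ripples only near the pyramidal layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import defaults

__all__ = ["DetectionParams", "RippleEvent", "detect_events", "label_duplicates", "events_to_frame"]


@dataclass(frozen=True)
class DetectionParams:
    band: tuple = defaults.SWR_BAND                  # Hz
    threshold_sd: float = defaults.SWR_THRESHOLD_SD  # peak threshold
    edge_sd: float = defaults.EDGE_THRESHOLD_SD      # event boundary threshold
    min_duration: float = defaults.SWR_MIN_DURATION  # s
    merge_gap: float = defaults.SWR_MERGE_GAP        # s
    smooth_band: tuple = defaults.ENVELOPE_SMOOTH_BAND  # Hz, envelope bandpass
    label: str = "SWR"

    @classmethod
    def swr(cls) -> "DetectionParams":
        return cls()

    @classmethod
    def high_gamma(cls) -> "DetectionParams":
        return cls(band=defaults.HIGH_GAMMA_BAND,
                   threshold_sd=defaults.SECONDARY_THRESHOLD_SD, label="highGamma")

    @classmethod
    def hfo(cls) -> "DetectionParams":
        return cls(band=defaults.HFO_BAND,
                   threshold_sd=defaults.SECONDARY_THRESHOLD_SD, label="HFO")


@dataclass
class RippleEvent:
    label: str
    start: float        # s
    peak: float         # s
    end: float          # s
    amplitude_sd: float  # envelope peak in SD units

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "RippleEvent") -> bool:
        return self.start < other.end and other.start < self.end


def _envelope(lfp: np.ndarray, fs: float, params: DetectionParams) -> np.ndarray:
    """Filter -> z-score -> rectify -> secondary 1-20 Hz bandpass."""
    lo, hi = params.band
    if hi >= fs / 2:
        raise ValueError(f"band {params.band} beyond Nyquist for fs={fs}")
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, lfp)
    z = (filt - filt.mean()) / filt.std()
    rect = np.abs(z)
    sos2 = sps.butter(4, params.smooth_band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos2, rect)


def _candidate_intervals(env: np.ndarray, fs: float, params: DetectionParams) -> list[tuple[int, int, int, float]]:
    """(start, peak, end, amp) index tuples from envelope thresholding."""
    mu, sd = env.mean(), env.std()
    peak_thr = mu + params.threshold_sd * sd
    edge_thr = mu + params.edge_sd * sd
    above_edge = env > edge_thr
    d = np.diff(above_edge.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above_edge[0]:
        starts = np.r_[0, starts]
    if above_edge[-1]:
        stops = np.r_[stops, len(env)]
    out = []
    for s, e in zip(starts, stops):
        seg = env[s:e]
        if seg.max() < peak_thr:
            continue
        p = s + int(np.argmax(seg))
        out.append((int(s), int(p), int(e), float((seg.max() - mu) / sd)))
    # merge events separated by less than the merge gap
    merged: list[list] = []
    gap = int(round(params.merge_gap * fs))
    for ev in out:
        if merged and ev[0] - merged[-1][2] < gap:
            last = merged[-1]
            if ev[3] > last[3]:
                last[1], last[3] = ev[1], ev[3]
            last[2] = ev[2]
        else:
            merged.append(list(ev))
    min_len = int(round(params.min_duration * fs))
    return [tuple(ev) for ev in merged if ev[2] - ev[0] >= min_len]


def detect_events(
    lfp: np.ndarray,
    noise_lfp: np.ndarray | None,
    fs: float,
    params: DetectionParams | None = None,
) -> list[RippleEvent]:
    """Detect band-limited transient events with noise-channel rejection.

    Candidates on the signal channel that overlap in time with any
    candidate detected on the noise channel (same procedure, same
    parameters) are removed.  Returned events are sorted by start time.
    """
    if params is None:
        params = DetectionParams.swr()
    lfp = np.asarray(lfp, dtype=float)
    env = _envelope(lfp, fs, params)
    cands = _candidate_intervals(env, fs, params)
    if noise_lfp is not None:
        noise_env = _envelope(np.asarray(noise_lfp, dtype=float), fs, params)
        noise_cands = _candidate_intervals(noise_env, fs, params)
        cands = [
            c for c in cands
            if not any(c[0] < ne and ns < c[2] for ns, _, ne, _ in noise_cands)
        ]
    return [
        RippleEvent(label=params.label, start=s / fs, peak=p / fs, end=e / fs, amplitude_sd=a)
        for s, p, e, a in cands
    ]


def label_duplicates(events_by_band: dict[str, list[RippleEvent]]) -> list[RippleEvent]:
    """Consolidate overlapping events across bands; SWR label dominates.

    Events are grouped into transitively-overlapping components.  A
    component containing at least one SWR collapses to a single SWR event
    spanning the component (peak taken from the strongest SWR member);
    components without an SWR keep their member events unchanged.
    """
    all_events = [ev for evs in events_by_band.values() for ev in evs]
    all_events.sort(key=lambda e: e.start)
    components: list[list[RippleEvent]] = []
    for ev in all_events:
        if components and ev.start < max(e.end for e in components[-1]):
            components[-1].append(ev)
        else:
            components.append([ev])
    out: list[RippleEvent] = []
    for comp in components:
        swrs = [e for e in comp if e.label == "SWR"]
        if swrs:
            best = max(swrs, key=lambda e: e.amplitude_sd)
            out.append(
                RippleEvent(
                    label="SWR",
                    start=min(e.start for e in comp),
                    peak=best.peak,
                    end=max(e.end for e in comp),
                    amplitude_sd=max(e.amplitude_sd for e in comp),
                )
            )
        else:
            out.extend(comp)
    out.sort(key=lambda e: e.start)
    return out


def events_to_frame(events: list[RippleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"label": e.label, "start_s": e.start, "peak_s": e.peak,
             "end_s": e.end, "amp_sd": e.amplitude_sd}
            for e in events
        ],
        columns=["label", "start_s", "peak_s", "end_s", "amp_sd"],
    )
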
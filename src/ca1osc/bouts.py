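"""Transient oscillatory-bout detection by joint amplitude/duration thresholding.

The detector follows the BOSC (Better OSCillation detection) logic: a
6-cycle Morlet wavelet spectrogram, a log-log linear fit of mean power
across frequency to capture the 1/f^x spectral tilt, a per-frequency
amplitude threshold at the 95th percentile of a chi-square(2) distribution
whose mean is pinned to the fitted background power, and a duration
threshold of 3 cycles.  Samples passing both thresholds are oscillatory
"hits"; everything else is a "miss".  Prevalence is summarised as the
occupancy rate (percent of time in detected episodes), also known as
P_episode(f).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import defaults

__all__ = [
    "WaveletSpectrogram",
    "BoutMask",
    "BoutTable",
    "default_freq_grid",
    "wavelet_power",
    "fit_background",
    "detect_bouts",
    "occupancy",
    "bout_durations",
    "duration_kde",
]


def default_freq_grid(
    fmin: float = defaults.BOUT_FREQS_MIN,
    fmax: float = defaults.BOUT_FREQS_MAX,
    n: int = defaults.BOUT_N_FREQS,
) -> np.ndarray:
    """Log-spaced wavelet frequency grid (default 29 points, 2-128 Hz)."""
    return np.geomspace(fmin, fmax, n)


@dataclass
class WaveletSpectrogram:
    freqs: np.ndarray               # Hz
    power: np.ndarray               # (n_freqs, n_samples)
    fs: float
    n_cycles: int = defaults.WAVELET_CYCLES
    edge: np.ndarray | None = None  # per-frequency edge width, samples

    def valid(self, fi: int) -> slice:
        """Interior samples unaffected by edge effects at frequency index fi."""
        e = int(self.edge[fi])
        return slice(e, self.power.shape[1] - e)


@dataclass
class BoutMask:
    freqs: np.ndarray
    hits: np.ndarray                # boolean (n_freqs, n_samples)
    fs: float
    amplitude_threshold: np.ndarray  # theta_A(f)
    duration_cycles: int = defaults.BOUT_DURATION_CYCLES


@dataclass
class BoutTable:
    band: str
    events: pd.DataFrame            # columns: start, end, duration (s)
    kde_bandwidth_ms: float | None = None


def wavelet_power(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: int = defaults.WAVELET_CYCLES,
) -> WaveletSpectrogram:
    """Morlet wavelet power with a fixed number of cycles per frequency.

    Wavelets are L2-normalised, so white noise yields an approximately flat
    expected power across frequency and power scales quadratically with
    signal amplitude.  Samples within one wavelet support of either edge
    are flagged invalid per frequency.
    """
    signal = np.asarray(signal, dtype=float)
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    n = signal.size
    power = np.empty((len(freqs), n))
    edge = np.empty(len(freqs), dtype=int)
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(3.5 * sigma_t * fs))
        tt = np.arange(-half, half + 1) / fs
        w = np.exp(2j * np.pi * f * tt) * np.exp(-(tt ** 2) / (2 * sigma_t ** 2))
        w -= w.mean()  # zero-mean (admissibility)
        w /= np.linalg.norm(w)
        conv = sps.fftconvolve(signal, w, mode="same")
        power[i] = np.abs(conv) ** 2
        edge[i] = min(half, n // 2)
    return WaveletSpectrogram(freqs=freqs, power=power, fs=fs, n_cycles=n_cycles, edge=edge)


def fit_background(
    spec: WaveletSpectrogram,
    exclude_bands: list[tuple[float, float]] | None = None,
    percentile: float = defaults.BOUT_AMPLITUDE_PCT,
) -> tuple[np.ndarray, float, float]:
    """Per-frequency amplitude threshold from a chi-square background model.

    Mean wavelet power (interior samples) is regressed on frequency in
    log-log space, optionally excluding known oscillation bands from the
    regression to avoid threshold inflation.  The threshold theta_A(f) is
    the requested percentile of a chi-square distribution with 2 degrees
    of freedom scaled so its mean equals the fitted background power —
    the distribution of wavelet power for Gaussian noise.

    Returns ``(theta_A, slope, intercept)`` of the log-log fit.
    """
    if len(spec.freqs) < 5:
        raise ValueError("need at least 5 frequencies to fit the background")
    mean_pow = np.array(
        [spec.power[i, spec.valid(i)].mean() for i in range(len(spec.freqs))]
    )
    mask = np.ones(len(spec.freqs), dtype=bool)
    for lo, hi in exclude_bands or []:
        mask &= ~((spec.freqs >= lo) & (spec.freqs <= hi))
    if mask.sum() < 2:
        raise ValueError("exclusion bands leave fewer than 2 frequencies")
    slope, intercept = np.polyfit(np.log10(spec.freqs[mask]), np.log10(mean_pow[mask]), 1)
    bg = 10 ** (intercept + slope * np.log10(spec.freqs))
    theta_a = bg * stats.chi2.ppf(percentile / 100.0, df=2) / 2.0
    return theta_a, float(slope), float(intercept)


def detect_bouts(
    spec: WaveletSpectrogram,
    theta_a: np.ndarray,
    duration_cycles: int = defaults.BOUT_DURATION_CYCLES,
) -> BoutMask:
    """Joint amplitude and duration thresholding into a hit/miss matrix.

    A sample is a hit at frequency f when power exceeds theta_A(f)
    continuously for at least ``duration_cycles`` cycles of f.  Samples in
    the per-frequency edge zones are never hits.
    """
    n_f, n = spec.power.shape
    hits = np.zeros((n_f, n), dtype=bool)
    for i, f in enumerate(spec.freqs):
        above = spec.power[i] > theta_a[i]
        v = spec.valid(i)
        above[: v.start] = False
        if v.stop < n:
            above[v.stop :] = False
        min_len = int(np.ceil(duration_cycles * spec.fs / f))
        hits[i] = _runs_at_least(above, min_len)
    return BoutMask(
        freqs=spec.freqs,
        hits=hits,
        fs=spec.fs,
        amplitude_threshold=np.asarray(theta_a),
        duration_cycles=duration_cycles,
    )


def _runs_at_least(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only True-runs of length >= min_len."""
    out = np.zeros_like(mask)
    if not mask.any():
        return out
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    for s, e in zip(starts, stops):
        if e - s >= min_len:
            out[s:e] = True
    return out


def occupancy(mask: BoutMask) -> np.ndarray:
    """Per-frequency occupancy rate, percent of total signal duration."""
    return 100.0 * mask.hits.mean(axis=1)


def bout_durations(
    mask: BoutMask,
    band: tuple[float, float],
    label: str = "",
    kde_bandwidth_ms: float | None = None,
) -> BoutTable:
    """Band-collapsed bout intervals with incomplete edge events removed.

    Frequency rows inside ``band`` are OR-collapsed into one binary series;
    start/stop transitions delimit events, and events missing a start or a
    stop (touching either end of the recording) are excluded.
    """
    rows = (mask.freqs >= band[0]) & (mask.freqs <= band[1])
    if not rows.any():
        raise ValueError(f"no frequencies inside band {band}")
    series = mask.hits[rows].any(axis=0)
    d = np.diff(series.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    # incomplete events at the boundaries have no observed start (or stop)
    if series[0]:
        stops = stops[1:] if stops.size else stops
    if series[-1]:
        starts = starts[:-1] if starts.size else starts
    n_ev = min(len(starts), len(stops))
    starts, stops = starts[:n_ev], stops[:n_ev]
    df = pd.DataFrame(
        {
            "start": starts / mask.fs,
            "end": stops / mask.fs,
            "duration": (stops - starts) / mask.fs,
        }
    )
    return BoutTable(band=label or f"{band[0]:g}-{band[1]:g}Hz", events=df,
                     kde_bandwidth_ms=kde_bandwidth_ms)


def duration_kde(durations_s: np.ndarray, bandwidth_ms: float):
    """Gaussian KDE over bout durations with an absolute bandwidth in ms.

    Returns a callable density over durations in seconds.
    """
    d = np.asarray(durations_s, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 durations for a KDE")
    bw_s = bandwidth_ms / 1000.0
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate durations (zero variance)")
    return stats.gaussian_kde(d, bw_method=bw_s / sd)
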
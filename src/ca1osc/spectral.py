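"""Welch spectral estimation and aperiodic/periodic parametrization.

The power spectrum of pyramidal-layer LFP is modelled in log10 space as a
linear aperiodic background, ``offset - exponent * log10(f)``, plus a sum
of Gaussian peaks (periodic components).  The flattened spectrum
(observed minus aperiodic) is the quantity compared across behavioural
states with a per-frequency paired Wilcoxon signed-rank test under
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from . import defaults

__all__ = [
    "PowerSpectrum",
    "SpectralModel",
    "SortedSpectralMap",
    "StateContrast",
    "welch_psd",
    "fit_spectral_model",
    "flatten",
    "sorted_spectral_map",
    "compare_states",
]

log = logging.getLogger(__name__)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray               # Hz, strictly increasing
    power: np.ndarray               # averaged PSD, linear units
    segments: np.ndarray | None = None  # (n_windows, n_freqs) per-window PSDs
    fs: float | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpectralModel:
    """Aperiodic + Gaussian-peak decomposition of a log-power spectrum."""

    offset: float                   # log10 power at 1 Hz
    exponent: float                 # 1/f^x slope
    peaks: list = field(default_factory=list)  # (center Hz, height log10, width Hz)
    freqs: np.ndarray | None = None
    residual: np.ndarray | None = None  # flattened spectrum on self.freqs

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component, log10 power."""
        return self.offset - self.exponent * np.log10(freqs)

    def peak_curve(self, freqs: np.ndarray) -> np.ndarray:
        """Sum of fitted Gaussians, log10 power."""
        out = np.zeros_like(np.asarray(freqs, dtype=float))
        for c, h, w in self.peaks:
            out += h * np.exp(-((freqs - c) ** 2) / (2 * w ** 2))
        return out

    def predict(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic(freqs) + self.peak_curve(freqs)


@dataclass
class SortedSpectralMap:
    matrix: np.ndarray              # (n_bins, n_freqs), ascending sort key
    freqs: np.ndarray
    sort_keys: np.ndarray           # per-bin mean sort-band power
    sort_band: tuple = defaults.SORT_BAND
    dropped: int = 0                # zero-median segments rejected


@dataclass
class StateContrast:
    freqs: np.ndarray
    statistic: np.ndarray           # per-frequency signed-rank statistic
    direction: np.ndarray           # sign of median(search - rest)
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray         # boolean, p_adj < alpha
    alpha: float = defaults.CONTRAST_ALPHA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq": self.freqs,
                "statistic": self.statistic,
                "direction": self.direction,
                "p": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.significant,
            }
        )


def welch_psd(
    signal: np.ndarray,
    fs: float,
    fmin: float = defaults.SPECTRUM_FMIN,
    fmax: float = defaults.SPECTRUM_FMAX,
    nperseg: int = defaults.WELCH_NPERSEG,
    overlap: float = defaults.WELCH_OVERLAP,
    df: float = defaults.SPECTRUM_DF,
) -> PowerSpectrum:
    """Welch PSD with 50%-overlapping Hann windows and per-window segments.

    Windows are zero-padded to an FFT length of ``fs / df`` samples so the
    output grid has the requested spacing; zero-padding only interpolates
    the same estimator and leaves Welch statistics unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    bad = np.flatnonzero(~np.isfinite(signal))
    if bad.size:
        raise ValueError(f"non-finite sample in signal at index {bad[0]}")
    if signal.size < 2 * nperseg:
        raise ValueError(f"signal must be at least {2 * nperseg} samples")
    nfft = max(nperseg, int(round(fs / df)))
    noverlap = int(round(nperseg * overlap))
    freqs, _, segs = sps.spectrogram(
        signal,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        mode="psd",
    )
    sel = (freqs >= fmin) & (freqs <= fmax)
    segments = segs[sel].T  # (n_windows, n_freqs)
    return PowerSpectrum(
        freqs=freqs[sel], power=segments.mean(axis=0), segments=segments, fs=fs
    )


def _gauss(f, c, h, w):
    return h * np.exp(-((f - c) ** 2) / (2 * w ** 2))


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Linear log-log fit, iteratively excluding positive-residual (peak) points."""
    mask = np.ones_like(logf, dtype=bool)
    coef = np.polyfit(logf, logp, 1)
    for _ in range(2):
        resid = logp - np.polyval(coef, logf)
        sd = resid.std()
        if sd == 0:
            break
        mask = resid < resid.mean() + 1.0 * sd
        if mask.sum() < 3:
            break
        coef = np.polyfit(logf[mask], logp[mask], 1)
    slope, intercept = coef
    return float(intercept), float(-slope)


def fit_spectral_model(
    spectrum: PowerSpectrum,
    fit_range: tuple = defaults.PARAM_FIT_RANGE,
    fit_df: float = defaults.PARAM_FIT_DF,
    peak_width_limits: tuple = defaults.PEAK_WIDTH_LIMITS,
    peak_threshold: float = defaults.PEAK_THRESHOLD,
    min_peak_height: float = defaults.MIN_PEAK_HEIGHT,
    max_n_peaks: int = defaults.MAX_N_PEAKS,
) -> SpectralModel:
    """Decompose a power spectrum into aperiodic background plus Gaussian peaks.

    Procedure: robust log-log linear fit of the background excluding
    peak-dominated frequencies; greedy extraction of Gaussians from the
    residual, tallest first (ties broken toward lower frequency), until the
    residual maximum falls below ``peak_threshold`` residual SDs; a joint
    bounded least-squares refit of all peaks; and a final plain refit of
    the background on the peak-subtracted spectrum.
    """
    if np.any(spectrum.power <= 0):
        raise ValueError("power must be strictly positive for log fitting")
    lo = max(fit_range[0], spectrum.freqs[0])
    hi = min(fit_range[1], spectrum.freqs[-1])
    grid = np.arange(lo, hi + fit_df / 2, fit_df)
    logp = np.interp(grid, spectrum.freqs, np.log10(spectrum.power))
    logf = np.log10(grid)

    offset, exponent = _robust_aperiodic(logf, logp)
    resid = logp - (offset - exponent * logf)

    peaks = []
    work = resid.copy()
    wmin, wmax = peak_width_limits
    for _ in range(max_n_peaks + 1):
        sd = work.std()
        i = int(np.argmax(work))  # argmax takes the first (lowest-f) tie
        h = work[i]
        if sd == 0 or h < peak_threshold * sd or h <= min_peak_height:
            break
        if len(peaks) >= max_n_peaks:
            warnings.warn(f"peak cap of {max_n_peaks} reached; stopping extraction")
            break
        # half-height span -> width guess
        half = h / 2
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < len(work) - 1 and work[ri] > half:
            ri += 1
        fwhm = max(grid[ri] - grid[li], fit_df)
        w0 = np.clip(fwhm / 2.355, wmin, wmax)
        try:
            popt, _ = curve_fit(
                _gauss,
                grid,
                work,
                p0=(grid[i], h, w0),
                bounds=([lo, 0.0, wmin], [hi, 3 * max(h, 1e-3), wmax]),
                maxfev=2000,
            )
        except RuntimeError:
            break
        peaks.append(tuple(popt))
        work = work - _gauss(grid, *popt)

    if peaks:
        p0 = np.concatenate(peaks)
        lb = np.tile([lo, 0.0, wmin], len(peaks))
        ub = np.tile([hi, np.inf, wmax], len(peaks))

        def multi(f, *params):
            out = np.zeros_like(f)
            for j in range(0, len(params), 3):
                out += _gauss(f, *params[j : j + 3])
            return out

        try:
            popt, _ = curve_fit(multi, grid, resid, p0=p0, bounds=(lb, ub), maxfev=5000)
            peaks = [tuple(popt[j : j + 3]) for j in range(0, len(popt), 3)]
        except RuntimeError:
            pass
        peak_model = np.zeros_like(grid)
        for c, h, w in peaks:
            peak_model += _gauss(grid, c, h, w)
    else:
        peak_model = np.zeros_like(grid)

    # final aperiodic refit on the peak-subtracted spectrum
    coef = np.polyfit(logf, logp - peak_model, 1)
    offset, exponent = float(coef[1]), float(-coef[0])
    model = SpectralModel(
        offset=offset,
        exponent=exponent,
        peaks=sorted(peaks, key=lambda p: p[0]),
        freqs=grid,
    )
    model.residual = logp - model.aperiodic(grid)
    return model


def flatten(spectrum: PowerSpectrum, model: SpectralModel) -> np.ndarray:
    """Flattened spectrum: log10 observed power minus the aperiodic fit."""
    if np.any(spectrum.power <= 0):
        raise ValueError("power must be strictly positive")
    return np.log10(spectrum.power) - model.aperiodic(spectrum.freqs)


def sorted_spectral_map(
    segments: np.ndarray,
    freqs: np.ndarray,
    sort_band: tuple = defaults.SORT_BAND,
    n_bins: int = defaults.N_SORT_BINS,
) -> SortedSpectralMap:
    """Quantile-binned spectral density map sorted by band power.

    Each per-window PSD segment is normalised by its own median, segments
    are sorted by mean power in ``sort_band``, and averaged into ``n_bins``
    equal-count (+/-1) bins in ascending order of the sort key.
    """
    segments = np.asarray(segments, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    med = np.median(segments, axis=1)
    keep = med > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropping %d zero-median segments", dropped)
    segments = segments[keep]
    if segments.shape[0] < n_bins:
        raise ValueError(f"need at least {n_bins} segments, got {segments.shape[0]}")
    norm = segments / np.median(segments, axis=1, keepdims=True)
    band = (freqs >= sort_band[0]) & (freqs <= sort_band[1])
    key = norm[:, band].mean(axis=1)
    order = np.argsort(key, kind="stable")
    chunks = np.array_split(order, n_bins)
    matrix = np.stack([norm[c].mean(axis=0) for c in chunks])
    keys = np.array([key[c].mean() for c in chunks])
    return SortedSpectralMap(
        matrix=matrix, freqs=freqs, sort_keys=keys, sort_band=sort_band, dropped=dropped
    )


def compare_states(
    search: np.ndarray,
    rest: np.ndarray,
    freqs: np.ndarray,
    alpha: float = defaults.CONTRAST_ALPHA,
) -> StateContrast:
    """Per-frequency paired Wilcoxon signed-rank contrast with BH-FDR control.

    ``search`` and ``rest`` are (n_sessions, n_freqs) arrays of paired
    per-session values (typically flattened power).  Direction is the sign
    of the median search-minus-rest difference.
    """
    search = np.atleast_2d(np.asarray(search, dtype=float))
    rest = np.atleast_2d(np.asarray(rest, dtype=float))
    if search.shape != rest.shape:
        raise ValueError("search and rest must be paired (same shape)")
    if search.shape[1] != len(freqs):
        raise ValueError("frequency grid does not match data columns")
    diffs = search - rest
    n_f = diffs.shape[1]
    stat = np.zeros(n_f)
    p_raw = np.ones(n_f)
    for j in range(n_f):
        d = diffs[:, j]
        if np.allclose(d, 0):
            stat[j], p_raw[j] = 0.0, 1.0
            continue
        res = stats.wilcoxon(d, zero_method="wilcox")
        stat[j], p_raw[j] = res.statistic, res.pvalue
    _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    p_adj = np.maximum(p_adj, p_raw)
    return StateContrast(
        freqs=np.asarray(freqs, dtype=float),
        statistic=stat,
        direction=np.sign(np.median(diffs, axis=0)),
        p_raw=p_raw,
        p_adj=p_adj,
        significant=p_adj < alpha,
        alpha=alpha,
    )
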
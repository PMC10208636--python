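"""Cross-frequency coupling: power comodulation, envelope correlation, bicoherence.

Three complementary views of how activity in different frequency bands
co-varies:

- the *power comodulogram*: Pearson correlation of per-window Welch power
  across every frequency pair, with a surrogate null built by shuffling
  the window order independently per frequency row;
- *Hilbert amplitude envelope correlation*: correlation of narrowband
  analytic amplitudes, tracking the same quantity continuously in time;
- *bicoherence*: the normalised bispectrum B(f1, f2), sensitive to
  quadratic phase coupling among triads (f1, f2, f1+f2), tested against a
  matched AR(1) ("red noise") null.

Significance in the two matrix statistics is cluster-corrected: cells
with uncorrected p < alpha are grouped by 4-connectivity (positive and
negative cells separately for signed statistics) and observed cluster
sizes are compared against the 95th percentile of the null distribution
of maximum cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from . import defaults

__all__ = [
    "Comodulogram",
    "ClusterTestResult",
    "BicoherenceMatrix",
    "power_comodulogram",
    "surrogate_cluster_test",
    "envelope_correlation",
    "bicoherence",
    "bicoherence_rednoise_test",
    "robust_mask",
]

_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class Comodulogram:
    freqs: np.ndarray
    corr: np.ndarray                # (F, F), symmetric, unit diagonal
    n_windows: int


@dataclass
class ClusterTestResult:
    p_uncorrected: np.ndarray       # per-cell p
    significant: np.ndarray         # cluster-corrected boolean mask
    cluster_sizes: list             # observed significant cluster sizes
    null_max_sizes: np.ndarray      # per-permutation max cluster size
    size_threshold: float           # 95th percentile of the null sizes
    n_permutations: int
    alpha: float


@dataclass
class BicoherenceMatrix:
    f1: np.ndarray                  # Hz
    f2: np.ndarray                  # Hz
    b: np.ndarray                   # (len(f1), len(f2)) in [0, 1]
    valid: np.ndarray               # False where f1 + f2 exceeds Nyquist
    n_segments: int
    fs: float


def power_comodulogram(segments: np.ndarray, freqs: np.ndarray) -> Comodulogram:
    """Pearson correlation of per-window power across all frequency pairs.

    ``segments`` is (n_windows, n_freqs) of per-window PSD values
    S_k(f_i); entry (i, j) is the correlation over windows k of
    (S_k(f_i) - mean_i) with (S_k(f_j) - mean_j), normalised by the two
    SDs.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.shape[0] < defaults.COMOD_MIN_WINDOWS:
        raise ValueError(
            f"need at least {defaults.COMOD_MIN_WINDOWS} windows, got {segments.shape[0]}"
        )
    corr = np.corrcoef(segments.T)
    return Comodulogram(freqs=np.asarray(freqs, float), corr=corr, n_windows=segments.shape[0])


def _signed_cluster_stats(
    matrix: np.ndarray,
    thr_hi: np.ndarray,
    thr_lo: np.ndarray,
    exclude: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Positive/negative suprathreshold masks and their cluster sizes."""
    pos = matrix > thr_hi
    neg = matrix < thr_lo
    if exclude is not None:
        pos &= ~exclude
        neg &= ~exclude
    sizes = []
    for m in (pos, neg):
        lab, n = ndimage.label(m, structure=_STRUCTURE)
        sizes.extend(np.bincount(lab.ravel())[1:].tolist() if n else [])
    return pos, neg, sizes


def _cluster_correct(
    obs: np.ndarray,
    null: np.ndarray,
    alpha: float,
    tail: str,
    exclude: np.ndarray | None = None,
) -> ClusterTestResult:
    """Cluster-based multiple-comparison correction against a null stack.

    ``null`` is (n_perm, *obs.shape).  Cells exceeding the per-cell null
    quantiles at level ``alpha`` (split across both tails when
    ``tail='two'``) are clustered by 4-connectivity; cluster sizes are
    referred to the 95th percentile of the per-permutation maximum
    cluster size under the same thresholds.
    """
    n_perm = null.shape[0]
    if n_perm == 0:
        raise ValueError("need at least one surrogate for a null distribution")
    if n_perm < 100:
        import warnings

        warnings.warn(f"only {n_perm} surrogates; null quantiles will be unstable")
    if tail == "two":
        thr_hi = np.quantile(null, 1 - alpha / 2, axis=0)
        thr_lo = np.quantile(null, alpha / 2, axis=0)
        ge = (null >= obs[None]).mean(axis=0)
        le = (null <= obs[None]).mean(axis=0)
        p = np.clip(2 * np.minimum(ge, le), 0, 1)
    elif tail == "high":
        thr_hi = np.quantile(null, 1 - alpha, axis=0)
        thr_lo = np.full_like(thr_hi, -np.inf)
        p = (null >= obs[None]).mean(axis=0)
    else:
        raise ValueError("tail must be 'two' or 'high'")

    pos, neg, obs_sizes = _signed_cluster_stats(obs, thr_hi, thr_lo, exclude)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        _, _, sizes = _signed_cluster_stats(null[i], thr_hi, thr_lo, exclude)
        null_max[i] = max(sizes) if sizes else 0
    size_thr = float(np.quantile(null_max, 0.95))

    sig = np.zeros_like(obs, dtype=bool)
    cluster_sizes = []
    for m in (pos, neg):
        lab, n = ndimage.label(m, structure=_STRUCTURE)
        for k in range(1, n + 1):
            size = int((lab == k).sum())
            cluster_sizes.append(size)
            # permutation p of the cluster against the max-size null
            p_clu = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
            if p_clu <= 0.05:
                sig |= lab == k
    return ClusterTestResult(
        p_uncorrected=p,
        significant=sig,
        cluster_sizes=cluster_sizes,
        null_max_sizes=null_max,
        size_threshold=size_thr,
        n_permutations=n_perm,
        alpha=alpha,
    )


def surrogate_cluster_test(
    segments: np.ndarray,
    freqs: np.ndarray,
    n_perm: int = defaults.N_PERMUTATIONS,
    alpha: float = defaults.CLUSTER_ALPHA,
    rng: np.random.Generator | None = None,
) -> tuple[Comodulogram, ClusterTestResult]:
    """Comodulogram plus surrogate-based cluster-corrected significance.

    Each surrogate shuffles the window order independently for every
    frequency row, destroying cross-frequency coupling while preserving
    each row's marginal distribution; the comodulogram of the shuffled
    data provides the per-cell null.  Positive and negative clusters are
    formed separately; the diagonal (trivially 1) is excluded.
    """
    if rng is None:
        rng = np.random.default_rng()
    como = power_comodulogram(segments, freqs)
    S = np.asarray(segments, dtype=float).T  # (F, K)
    n_f, n_k = S.shape
    null = np.empty((n_perm, n_f, n_f), dtype=np.float32)
    for i in range(n_perm):
        idx = np.argsort(rng.random((n_f, n_k)), axis=1)
        null[i] = np.corrcoef(np.take_along_axis(S, idx, axis=1))
    exclude = np.eye(n_f, dtype=bool)
    res = _cluster_correct(como.corr, null, alpha, tail="two", exclude=exclude)
    return como, res


def envelope_correlation(
    signal: np.ndarray,
    fs: float,
    f_i: float,
    f_j: float,
    bandwidth: float = defaults.ENVELOPE_BANDWIDTH,
    order: int = defaults.ENVELOPE_FILTER_ORDER,
) -> float:
    """Correlation of Hilbert amplitude envelopes at two frequencies.

    Each band is isolated with a zero-phase Butterworth bandpass of the
    given order and ``bandwidth`` (f +/- bandwidth/2); the analytic
    amplitude envelopes are then Pearson-correlated.
    """
    signal = np.asarray(signal, dtype=float)
    envs = []
    for f in (f_i, f_j):
        lo, hi = f - bandwidth / 2, f + bandwidth / 2
        if lo <= 0 or hi >= fs / 2:
            raise ValueError(f"band {lo}-{hi} Hz outside (0, Nyquist)")
        sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
        envs.append(np.abs(sps.hilbert(sps.sosfiltfilt(sos, signal))))
    return float(np.corrcoef(envs[0], envs[1])[0, 1])


def _segment_fft(signal: np.ndarray, fs: float, seglen: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered 50%-overlapping segment FFT coefficients F_t(f)."""
    step = seglen // 2
    n_seg = (len(signal) - seglen) // step + 1
    if n_seg < 1:
        raise ValueError("signal shorter than one segment")
    win = np.hanning(seglen)
    idx = np.arange(seglen)[None, :] + step * np.arange(n_seg)[:, None]
    segs = signal[idx] * win
    coefs = np.fft.rfft(segs, axis=1)
    freqs = np.fft.rfftfreq(seglen, d=1.0 / fs)
    return coefs, freqs


def bicoherence(
    signal: np.ndarray,
    fs: float,
    f1_max: float = defaults.BICOH_F1_MAX,
    f2_max: float = defaults.BICOH_F2_MAX,
    seglen: int = defaults.BICOH_SEGLEN,
) -> BicoherenceMatrix:
    """Normalised bispectrum B(f1, f2) over Hann-tapered segments.

    B = |<F(f1) F(f2) F*(f1+f2)>| / <|F(f1) F(f2) F*(f1+f2)|>, averaged
    over segments; bounded in [0, 1] and equal to 1 for perfect quadratic
    phase coupling.  Requested 1 Hz-step grids are mapped to the nearest
    FFT bins of the ``seglen``-sample segments; cells with f1 + f2 above
    Nyquist are flagged invalid.
    """
    signal = np.asarray(signal, dtype=float)
    coefs, freqs = _segment_fft(signal, fs, seglen)
    n_seg = coefs.shape[0]
    if n_seg < 2:
        raise ValueError("need at least 2 segments")
    dfreq = fs / seglen
    k1 = np.round(np.arange(1.0, f1_max + 0.5) / dfreq).astype(int)
    k2 = np.round(np.arange(1.0, f2_max + 0.5) / dfreq).astype(int)
    kmax = coefs.shape[1] - 1
    ksum = k1[:, None] + k2[None, :]
    valid = ksum <= kmax
    ksum_c = np.minimum(ksum, kmax)
    T = coefs[:, k1][:, :, None] * coefs[:, k2][:, None, :] * np.conj(coefs[:, ksum_c])
    num = np.abs(T.mean(axis=0))
    den = np.abs(T).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(den > 0, num / den, 0.0)
    b = np.where(valid, b, 0.0)
    return BicoherenceMatrix(
        f1=k1 * dfreq, f2=k2 * dfreq, b=b, valid=valid, n_segments=n_seg, fs=fs
    )


def fit_ar1(signal: np.ndarray) -> tuple[float, float]:
    """Lag-1 autocorrelation and variance of a signal (red-noise parameters)."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    var = x.var()
    phi = float(np.dot(x[:-1], x[1:]) / np.dot(x[:-1], x[:-1]))
    phi = float(np.clip(phi, -0.999, 0.999))
    return phi, float(var)


def ar1_surrogate(n: int, phi: float, var: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) sample of length n with the given lag-1 coefficient and variance."""
    e = rng.standard_normal(n) * np.sqrt(var * (1 - phi ** 2))
    return sps.lfilter([1.0], [1.0, -phi], e)


def bicoherence_rednoise_test(
    signal: np.ndarray,
    fs: float,
    n_surrogates: int = defaults.N_PERMUTATIONS,
    alpha: float = defaults.CLUSTER_ALPHA,
    rng: np.random.Generator | None = None,
    **bic_kwargs,
) -> tuple[BicoherenceMatrix, ClusterTestResult]:
    """Bicoherence with a cluster-corrected red-noise (AR(1)) null.

    Surrogates are AR(1) processes matched to the signal's lag-1
    autocorrelation and variance; each is run through the same
    bicoherence estimator to build the per-cell null, followed by the
    cluster-size correction (high tail only — bicoherence is
    non-negative).
    """
    if n_surrogates <= 0:
        raise ValueError("need at least one surrogate")
    if rng is None:
        rng = np.random.default_rng()
    obs = bicoherence(signal, fs, **bic_kwargs)
    phi, var = fit_ar1(signal)
    null = np.empty((n_surrogates,) + obs.b.shape, dtype=np.float32)
    for i in range(n_surrogates):
        surro = ar1_surrogate(len(signal), phi, var, rng)
        null[i] = bicoherence(surro, fs, **bic_kwargs).b
    res = _cluster_correct(obs.b, null, alpha, tail="high", exclude=~obs.valid)
    return obs, res


def robust_mask(masks: list[np.ndarray], fraction: float = defaults.ROBUST_FRACTION) -> np.ndarray:
    """Cells significant in at least ``fraction`` of the provided samples."""
    if not masks:
        raise ValueError("no masks provided")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    return stack.mean(axis=0) >= fraction
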
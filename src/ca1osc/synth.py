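"""Synthetic CA1 session generator with ground truth.

Generates recording sessions that share the statistical structure the
analysis chain assumes — a 1/f^x aperiodic LFP background, state-dependent
transient narrowband bouts, sharp-wave-ripple (SWR) complexes, and spike
trains phase-locked to chosen bands — together with exact ground-truth
tables, so every downstream stage can be validated without real data.

All randomness flows from a single integer seed fanned out into
independent per-component substreams (:class:`numpy.random.SeedSequence`
spawning), so a config is bit-reproducible while components stay
statistically independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps
from scipy.special import i0

__all__ = [
    "BoutSpec",
    "SwrSpec",
    "UnitSpec",
    "SynthConfig",
    "SessionBundle",
    "gen_aperiodic",
    "gen_bouts",
    "gen_swrs",
    "gen_spikes",
    "generate_session",
]

STATE_LABELS = ("search", "rest")


@dataclass(frozen=True)
class BoutSpec:
    """One transient narrowband oscillation class.

    Parameters
    ----------
    freq : center frequency, Hz.
    bandwidth : Hz; per-bout frequency drawn uniformly in freq +/- bandwidth/2.
    rates : bouts per minute, keyed by state label.
    duration_mean, duration_sd : lognormal bout-duration parameters, s.
    amplitude_sd : bout amplitude as a multiple of the background SD.
    label : band name used in the truth table.
    """

    freq: float
    bandwidth: float = 0.0
    rates: dict = field(default_factory=dict)
    duration_mean: float = 1.0
    duration_sd: float = 0.3
    amplitude_sd: float = 2.5
    label: str = ""

    def name(self) -> str:
        return self.label or f"{self.freq:g}Hz"


@dataclass(frozen=True)
class SwrSpec:
    """Sharp-wave-ripple event class: slow biphasic deflection + ripple burst.

    ``ripple_duration`` and ``ripple_amplitude_sd`` may be scalars or
    (lo, hi) tuples; tuples draw a uniform value per event, mimicking the
    natural spread of ripple sizes.
    """

    rates: dict = field(default_factory=dict)   # events per minute per state
    ripple_freq: float = 140.0                  # Hz
    ripple_duration: float | tuple = 0.080      # s
    ripple_amplitude_sd: float | tuple = 5.0    # x SD of 100-250 Hz background
    sharpwave_amplitude_sd: float = 3.0         # x SD of broadband background
    sharpwave_width: float = 0.080              # s (Gaussian sigma of the lobes)

    def max_duration(self) -> float:
        d = self.ripple_duration
        return d[1] if isinstance(d, (tuple, list)) else d


@dataclass(frozen=True)
class UnitSpec:
    """One simulated unit.

    Firing follows an inhomogeneous Poisson process with rate

        r(t) = base_rate * exp(kappa * cos(theta_f(t))) / I0(kappa) * g(t)

    where theta_f is the phase of the (noiseless) target-band oscillator and
    g(t) = swr_gain inside ground-truth SWR windows, 1 elsewhere.  The von
    Mises normalisation keeps the time-averaged rate at base_rate when
    swr_gain = 1.  With ``lock_in_swr_only`` the phase modulation applies
    only inside the SWR windows — the confound case where apparent
    low-frequency spike-field locking is carried entirely by SWRs.
    """

    base_rate: float
    locked_freq: float | None = None
    kappa: float = 0.0
    swr_gain: float = 1.0
    lock_in_swr_only: bool = False


@dataclass(frozen=True)
class SynthConfig:
    sampling_rate: float = 1000.0   # Hz
    duration: float = 600.0         # s
    aperiodic_exponent: float = 1.5  # x in 1/f^x
    aperiodic_offset: float = 0.0   # log10 power at 1 Hz (arbitrary units)
    state_plan: tuple = ()          # ((label, start_s, end_s), ...)
    bout_specs: tuple = ()          # BoutSpec, ...
    swr_spec: SwrSpec | None = None
    unit_specs: tuple = ()          # UnitSpec, ...
    seed: int = 0

    def validate(self) -> None:
        fs, dur = self.sampling_rate, self.duration
        for v in (fs, dur, self.aperiodic_exponent, self.aperiodic_offset):
            if not np.isfinite(v):
                raise ValueError("non-finite config value")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic exponent must be >= 0")
        if dur * fs < 2 ** 12:
            raise ValueError("session must contain at least 4096 samples")
        ivals = sorted((s, e) for _, s, e in self.state_plan)
        for (s, e) in ivals:
            if not (0 <= s < e <= dur):
                raise ValueError(f"state interval ({s}, {e}) outside [0, {dur}]")
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("state intervals overlap")
        for lbl, _, _ in self.state_plan:
            if lbl not in STATE_LABELS:
                raise ValueError(f"unknown state label {lbl!r}")
        top = max(
            [b.freq + b.bandwidth / 2 for b in self.bout_specs]
            + ([self.swr_spec.ripple_freq] if self.swr_spec else [])
            + [0.0]
        )
        if top > 0 and fs < 4 * top:
            raise ValueError("sampling_rate must be >= 4x highest generated frequency")
        for b in self.bout_specs:
            if any(r < 0 for r in b.rates.values()) or b.duration_mean <= 0:
                raise ValueError("bout rates must be >= 0 and durations > 0")
        for u in self.unit_specs:
            if u.kappa < 0 or u.base_rate < 0:
                raise ValueError("unit kappa and base rate must be >= 0")
            if u.locked_freq is not None and u.locked_freq > fs / 2:
                raise ValueError("locked frequency above Nyquist")

    def state_intervals(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for lbl, s, e in self.state_plan if lbl == label]


@dataclass
class SessionBundle:
    """One synthetic recording session plus ground truth."""

    config: SynthConfig
    lfp: np.ndarray                 # (n_channels, n_samples)
    noise_channel: np.ndarray       # (n_samples,)
    spikes: dict                    # unit id -> sorted spike times, s
    states: pd.DataFrame            # columns: state, start, end
    truth_bouts: pd.DataFrame       # columns: band, freq, start, end, state, truncated
    truth_swrs: pd.DataFrame        # columns: start, peak, end, state
    phase_tracks: dict = field(default_factory=dict)  # freq -> phase(t), radians

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate

    @property
    def duration(self) -> float:
        return self.config.duration

    def to_dir(self, outdir: str | Path) -> None:
        """Write the bundle as an HDF5 container plus CSV sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with h5py.File(outdir / "session.h5", "w") as h5:
            h5.create_dataset("lfp", data=self.lfp)
            h5.create_dataset("noise_channel", data=self.noise_channel)
            h5.attrs["sampling_rate"] = self.sampling_rate
            h5.attrs["duration"] = self.duration
        rows = [
            {"unit_id": uid, "time_s": t}
            for uid, times in sorted(self.spikes.items())
            for t in times
        ]
        pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
            outdir / "spikes.csv", index=False
        )
        self.states.to_csv(outdir / "states.csv", index=False)
        self.truth_bouts.to_csv(outdir / "truth_bouts.csv", index=False)
        self.truth_swrs.to_csv(outdir / "truth_swrs.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(self.config), fh, sort_keys=False)

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "SessionBundle":
        outdir = Path(outdir)
        with h5py.File(outdir / "session.h5", "r") as h5:
            lfp = h5["lfp"][...]
            noise = h5["noise_channel"][...]
        sp = pd.read_csv(outdir / "spikes.csv")
        spikes = {
            int(uid): np.sort(g["time_s"].to_numpy())
            for uid, g in sp.groupby("unit_id")
        }
        with open(outdir / "config.yaml") as fh:
            config = _config_from_dict(yaml.safe_load(fh))
        return cls(
            config=config,
            lfp=lfp,
            noise_channel=noise,
            spikes=spikes,
            states=pd.read_csv(outdir / "states.csv"),
            truth_bouts=pd.read_csv(outdir / "truth_bouts.csv"),
            truth_swrs=pd.read_csv(outdir / "truth_swrs.csv"),
        )


def _config_to_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["state_plan"] = [list(x) for x in cfg.state_plan]
    d["bout_specs"] = [dataclasses.asdict(b) for b in cfg.bout_specs]
    d["unit_specs"] = [dataclasses.asdict(u) for u in cfg.unit_specs]
    d["swr_spec"] = dataclasses.asdict(cfg.swr_spec) if cfg.swr_spec else None
    return d


def _config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    d["state_plan"] = tuple(tuple(x) for x in d.get("state_plan", ()))
    d["bout_specs"] = tuple(BoutSpec(**b) for b in d.get("bout_specs", ()))
    d["unit_specs"] = tuple(UnitSpec(**u) for u in d.get("unit_specs", ()))
    sw = d.get("swr_spec")
    d["swr_spec"] = SwrSpec(**sw) if sw else None
    return SynthConfig(**d)


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def _substream(cfg: SynthConfig, index: int) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(8)
    return np.random.default_rng(children[index])


def gen_aperiodic(config: SynthConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """1/f^x background by inverse-FFT spectral shaping of white noise.

    The expected log10 power spectrum is ``offset - exponent * log10(f)``;
    the exponent is exact by construction (each Fourier coefficient is
    scaled deterministically), which makes this the natural inverse of the
    aperiodic component of the spectral parametrization.
    """
    config.validate()
    if rng is None:
        rng = _substream(config, 0)
    n = int(round(config.duration * config.sampling_rate))
    white = rng.standard_normal(n)
    coef = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    # amplitude scaling: power ~ 10^offset * f^-x
    scale[nz] = np.sqrt(10.0 ** config.aperiodic_offset * freqs[nz] ** (-config.aperiodic_exponent))
    x = np.fft.irfft(coef * scale, n=n)
    return x - x.mean()


def _poisson_starts(
    rng: np.random.Generator,
    intervals: list[tuple[float, float]],
    rate_per_min: float,
) -> np.ndarray:
    """Homogeneous Poisson event starts inside the given intervals."""
    out = []
    for s, e in intervals:
        lam = rate_per_min / 60.0 * (e - s)
        k = rng.poisson(lam)
        out.append(np.sort(rng.uniform(s, e, size=k)))
    return np.concatenate(out) if out else np.array([])


def gen_bouts(
    config: SynthConfig,
    background_sd: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Place Hann-tapered narrowband bouts by a per-state Poisson process.

    Returns the additive bout signal, the ground-truth bout table, and the
    noiseless phase track per locked frequency (used for spike locking).
    Bouts that would outrun their state interval are truncated and flagged.
    """
    config.validate()
    if rng is None:
        rng = _substream(config, 1)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    rows = []
    phase_tracks: dict[float, np.ndarray] = {}
    for spec in config.bout_specs:
        # one continuous global oscillator phase per bout class so that
        # in-bout LFP phase and spike-locking phase agree exactly
        phi0 = rng.uniform(0, 2 * np.pi)
        phase_tracks[spec.freq] = 2 * np.pi * spec.freq * t + phi0
        for state, s0, e0 in config.state_plan:
            rate = spec.rates.get(state, 0.0)
            if rate <= 0:
                continue
            starts = _poisson_starts(rng, [(s0, e0)], rate)
            for start in starts:
                mu = np.log(spec.duration_mean**2 / np.sqrt(spec.duration_mean**2 + spec.duration_sd**2))
                sdl = np.sqrt(np.log(1 + spec.duration_sd**2 / spec.duration_mean**2))
                dur = float(np.exp(rng.normal(mu, sdl)))
                truncated = start + dur > e0
                end = min(start + dur, e0)
                f_b = spec.freq + spec.bandwidth * (rng.uniform() - 0.5)
                i0_, i1_ = int(round(start * fs)), int(round(end * fs))
                if i1_ - i0_ < 4:
                    continue
                seg = np.arange(i0_, i1_)
                taper = np.hanning(i1_ - i0_)
                if abs(f_b - spec.freq) < 1e-9:
                    carrier = np.cos(phase_tracks[spec.freq][seg])
                else:
                    carrier = np.cos(2 * np.pi * f_b * t[seg] + phi0)
                sig[seg] += spec.amplitude_sd * background_sd * taper * carrier
                rows.append(
                    {
                        "band": spec.name(),
                        "freq": f_b,
                        "start": start,
                        "end": end,
                        "state": state,
                        "truncated": bool(truncated),
                    }
                )
    cols = ["band", "freq", "start", "end", "state", "truncated"]
    truth = pd.DataFrame(rows, columns=cols).sort_values("start").reset_index(drop=True)
    return sig, truth, phase_tracks


def _sharpwave_waveform(width: float, fs: float) -> np.ndarray:
    """Biphasic slow deflection: difference of two offset Gaussians.

    Energy is confined below ~10 Hz for widths in the 60-100 ms range.
    """
    half = int(round(3 * width * fs))
    tt = np.arange(-half, half + 1) / fs
    g1 = np.exp(-((tt + width / 3) ** 2) / (2 * (width / 2) ** 2))
    g2 = np.exp(-((tt - width / 3) ** 2) / (2 * (width / 2) ** 2))
    w = g1 - 0.6 * g2
    return w / np.abs(w).max()


def gen_swrs(
    config: SynthConfig,
    background: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Inject SWR complexes (slow deflection + ripple burst), Poisson per state.

    Ripple amplitude is calibrated in SD units of the ripple-band
    (100-250 Hz) filtered background; the slow component in SD units of the
    broadband background.  Colliding events are resampled (non-overlap).
    """
    config.validate()
    if rng is None:
        rng = _substream(config, 2)
    fs = config.sampling_rate
    n = len(background)
    sig = np.zeros(n)
    spec = config.swr_spec
    if spec is None:
        return sig, pd.DataFrame(columns=["start", "peak", "end", "state"])
    sos = sps.butter(4, (100.0, min(250.0, 0.45 * fs)), btype="bandpass", fs=fs, output="sos")
    ripple_band_sd = float(np.std(sps.sosfiltfilt(sos, background)))
    broad_sd = float(np.std(background))
    sw = _sharpwave_waveform(spec.sharpwave_width, fs)
    half_sw = (len(sw) - 1) // 2
    event_len = max(len(sw), int(round(spec.max_duration() * fs)))

    def _draw(v):
        return rng.uniform(*v) if isinstance(v, (tuple, list)) else v

    rows = []
    occupied: list[tuple[float, float]] = []
    for state, s0, e0 in config.state_plan:
        rate = spec.rates.get(state, 0.0)
        if rate <= 0:
            continue
        starts = _poisson_starts(rng, [(s0, e0)], rate)
        for peak_t in starts:
            ok = False
            for _ in range(20):  # resample on collision
                lo, hi = peak_t - event_len / fs, peak_t + event_len / fs
                if all(hi <= a or lo >= b for a, b in occupied) and s0 < peak_t < e0:
                    ok = True
                    break
                peak_t = rng.uniform(s0, e0)
            if not ok:
                continue
            occupied.append((peak_t - event_len / fs, peak_t + event_len / fs))
            c = int(round(peak_t * fs))
            i0_, i1_ = c - half_sw, c + half_sw + 1
            if i0_ < 0 or i1_ > n:
                continue
            if spec.sharpwave_amplitude_sd > 0:
                sig[i0_:i1_] += spec.sharpwave_amplitude_sd * broad_sd * sw
            dur = _draw(spec.ripple_duration)
            amp = _draw(spec.ripple_amplitude_sd)
            rl = int(round(dur * fs))
            r0 = c - rl // 2
            if amp > 0 and r0 >= 0 and r0 + rl <= n:
                tt = np.arange(rl) / fs
                # flat-top taper: a ripple burst sustains its envelope through
                # the event, so "amplitude in SD" holds across the burst core
                ripple = (
                    amp
                    * ripple_band_sd
                    * sps.windows.tukey(rl, 0.4)
                    * np.cos(2 * np.pi * spec.ripple_freq * tt + rng.uniform(0, 2 * np.pi))
                )
                sig[r0 : r0 + rl] += ripple
            rows.append(
                {
                    "start": peak_t - dur / 2,
                    "peak": peak_t,
                    "end": peak_t + dur / 2,
                    "state": state,
                }
            )
    truth = pd.DataFrame(rows, columns=["start", "peak", "end", "state"]).sort_values("start").reset_index(drop=True)
    return sig, truth


def gen_spikes(
    config: SynthConfig,
    phase_tracks: dict,
    truth_swrs: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict:
    """Inhomogeneous Poisson spike trains with von Mises phase locking.

    rate(t) = base * exp(kappa cos(theta(t))) / I0(kappa) * gain(t); the
    normalisation keeps the time-averaged rate at the base rate when the
    SWR gain is 1.  Spikes are drawn by thinning.
    """
    config.validate()
    if rng is None:
        rng = _substream(config, 3)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    swr_mask = np.zeros(n, dtype=bool)
    for _, row in truth_swrs.iterrows():
        a = max(0, int(round((row["peak"] - 0.3) * fs)))
        b = min(n, int(round((row["peak"] + 0.3) * fs)))
        swr_mask[a:b] = True
    spikes = {}
    for uid, u in enumerate(config.unit_specs):
        if u.base_rate == 0:
            spikes[uid] = np.array([])
            continue
        rmax = u.base_rate * (np.exp(u.kappa) / i0(u.kappa)) * max(u.swr_gain, 1.0)
        k = rng.poisson(rmax * config.duration)
        cand = np.sort(rng.uniform(0, config.duration, size=k))
        idx = np.minimum((cand * fs).astype(int), n - 1)
        rate = np.full(len(cand), u.base_rate)
        if u.locked_freq is not None and u.kappa > 0:
            if u.locked_freq not in phase_tracks:
                phase = 2 * np.pi * u.locked_freq * cand
            else:
                phase = phase_tracks[u.locked_freq][idx]
            mod = np.exp(u.kappa * np.cos(phase)) / i0(u.kappa)
            if u.lock_in_swr_only:
                rate = rate * np.where(swr_mask[idx], mod, 1.0)
            else:
                rate = rate * mod
        if u.swr_gain != 1.0:
            rate = rate * np.where(swr_mask[idx], u.swr_gain, 1.0)
        keep = rng.uniform(size=len(cand)) < rate / rmax
        st = cand[keep]
        spikes[uid] = st[(st > 0) & (st < config.duration)]
    return spikes


def generate_session(config: SynthConfig) -> SessionBundle:
    """Generate a full session: background + bouts + SWRs + noise channel + spikes."""
    config.validate()
    rngs = [np.random.default_rng(c) for c in np.random.SeedSequence(config.seed).spawn(8)]
    background = gen_aperiodic(config, rngs[0])
    bg_sd = float(np.std(background))
    bout_sig, truth_bouts, phase_tracks = gen_bouts(config, bg_sd, rngs[1])
    swr_sig, truth_swrs = gen_swrs(config, background, rngs[2])
    lfp = (background + bout_sig + swr_sig)[None, :]
    # independent aperiodic process on the distant "noise detecting" channel
    noise = gen_aperiodic(config, rngs[4])
    spikes = gen_spikes(config, phase_tracks, truth_swrs, rngs[3])
    states = pd.DataFrame(
        [{"state": s, "start": a, "end": b} for s, a, b in config.state_plan],
        columns=["state", "start", "end"],
    )
    return SessionBundle(
        config=config,
        lfp=lfp,
        noise_channel=noise,
        spikes=spikes,
        states=states,
        truth_bouts=truth_bouts,
        truth_swrs=truth_swrs,
        phase_tracks=phase_tracks,
    )


def gen_envelope_coupled_signal(
    fs: float,
    duration: float,
    carrier_freqs: tuple = (5.0, 30.0, 100.0),
    rho: tuple = (-0.7, 0.7),
    depth: float = 0.3,
    mod_bandwidth: float = 0.25,
    base_amplitude: float = 1.0,
    noise_sd: float = 0.1,
    carrier_bands: tuple | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Three amplitude-modulated carriers with controlled power correlations.

    The squared amplitude (power) of each carrier is a slow positive
    process 1 + depth * g_i(t), where the g_i are unit-variance Gaussian
    processes lowpass-filtered to ``mod_bandwidth`` Hz with *in-sample*
    correlations pinned by Gram-Schmidt construction to
    corr(g0, g1) = rho[0] and corr(g0, g2) = rho[1]; because the power is
    linear in g (the rare negative excursions are clipped), the Pearson
    correlation of the powers equals the targets to within the clipping
    error.  Slow modulation keeps spectral splatter — which would induce
    spurious broadband comodulation — negligible.

    With ``carrier_bands`` (three (lo_hz, hi_hz, relative_amplitude)
    tuples) each tone is accompanied by band-limited noise sharing its
    modulator, so comodulation spans a frequency *band* as in real LFP
    rather than a single bin.

    Returns ``(signal, powers)`` with powers of shape (n_samples, 3).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    def slow_gauss():
        # FFT-domain Gaussian lowpass: numerically stable at extreme
        # bandwidth/fs ratios where IIR filters are not
        w = rng.standard_normal(n)
        coef = np.fft.rfft(w)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        g = np.fft.irfft(coef * np.exp(-((f / mod_bandwidth) ** 2)), n=n)
        return (g - g.mean()) / g.std()

    def orthogonal_to(g, ref):
        # slow modulators have few effective DOF per session, so pin the
        # in-sample correlation rather than the population one
        g = g - (g @ ref) / (ref @ ref) * ref
        return (g - g.mean()) / g.std()

    g0 = slow_gauss()
    r01, r02 = rho
    g1 = r01 * g0 + np.sqrt(1 - r01 ** 2) * orthogonal_to(slow_gauss(), g0)
    g2 = r02 * g0 + np.sqrt(1 - r02 ** 2) * orthogonal_to(slow_gauss(), g0)
    powers = base_amplitude ** 2 * np.maximum(
        1.0 + depth * np.stack([g0, g1, g2], axis=1), 0.05
    )
    sig = noise_sd * rng.standard_normal(n)
    for i, f in enumerate(carrier_freqs):
        sig += np.sqrt(powers[:, i]) * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if carrier_bands is not None:
            lo, hi, amp = carrier_bands[i]
            coef = np.fft.rfft(rng.standard_normal(n))
            fr = np.fft.rfftfreq(n, d=1.0 / fs)
            nb = np.fft.irfft(coef * ((fr >= lo) & (fr <= hi)), n=n)
            # amplitude ~ p (power ~ p^2): deeper band modulation so
            # per-bin power correlations survive the chi-square estimation
            # noise and form contiguous significant clusters; keep the band
            # clear of the tone's spectral main lobe so the tone bin stays
            # a clean readout of the modulator
            a = powers[:, i] / np.sqrt((powers[:, i] ** 2).mean())
            sig += amp * a * nb / nb.std()
    return sig, powers


def gen_coupled_triad(
    fs: float,
    n_segments: int,
    seglen: int = 1024,
    f1: float = 20.0,
    f2: float = 40.0,
    coupled: bool = True,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Segment-wise triad of tones at (f1, f2, f1+f2) for bicoherence tests.

    Each non-overlapping ``seglen``-sample piece carries three cosines with
    fresh random phases phi1, phi2; when ``coupled`` the third tone's phase
    is phi1 + phi2 (perfect quadratic phase coupling, bicoherence -> 1 at
    (f1, f2)), otherwise it is independent (bicoherence -> 0).
    """
    if rng is None:
        rng = np.random.default_rng()
    tt = np.arange(seglen) / fs
    pieces = []
    for _ in range(n_segments):
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        p3 = p1 + p2 if coupled else rng.uniform(0, 2 * np.pi)
        x = (
            np.cos(2 * np.pi * f1 * tt + p1)
            + np.cos(2 * np.pi * f2 * tt + p2)
            + np.cos(2 * np.pi * (f1 + f2) * tt + p3)
            + noise_sd * rng.standard_normal(seglen)
        )
        pieces.append(x)
    return np.concatenate(pieces)


def truth_occupancy(truth_bouts: pd.DataFrame, band: str, intervals: list[tuple[float, float]]) -> float:
    """Percent of the given intervals covered by ground-truth bouts of a band.

    Overlapping bouts are merged before summing so coverage is a true
    fraction of time.
    """
    total = sum(e - s for s, e in intervals)
    if total <= 0:
        return 0.0
    sel = truth_bouts[truth_bouts["band"] == band]
    clipped = []
    for _, row in sel.iterrows():
        for s, e in intervals:
            a, b = max(row["start"], s), min(row["end"], e)
            if b > a:
                clipped.append((a, b))
    if not clipped:
        return 0.0
    clipped.sort()
    merged = [list(clipped[0])]
    for a, b in clipped[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return 100.0 * sum(b - a for a, b in merged) / total
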
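"""Configuration-driven orchestration of the full analysis chain.

A run is described by a structured-text (YAML) config naming the stages
to execute, the synthetic-session block (or an existing session
directory), a global seed, and per-stage parameter overrides; omitted
parameters fall back to the defaults table.  Stages execute in
dependency order (synthgen -> spectral / bouts / swr -> crossfreq /
spikefield -> rhythmicity), every source of randomness derives from the
global seed through fixed per-stage substreams, and a JSON manifest
records parameters, outputs, input digests and status per stage, so a
run is fully reproducible and any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import bouts as boutsmod
from . import crossfreq, defaults, rhythmicity, spectral, spikefield
from . import swr as swrmod
from .synth import SessionBundle, SynthConfig, _config_from_dict, generate_session

__all__ = ["RunConfig", "RunManifest", "run", "demo_config", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("synthgen", "spectral", "bouts", "swr", "crossfreq", "spikefield", "rhythmicity")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple = STAGES
    synth: SynthConfig | None = None
    params: dict = field(default_factory=dict)  # stage -> overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        synth_cfg = None
        if "synth" in raw:
            d = dict(raw["synth"])
            d.setdefault("seed", raw.get("seed", 0))
            synth_cfg = _config_from_dict(d)
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", STAGES)),
            synth=synth_cfg,
            params=raw.get("params", {}),
        )

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; valid stages: {STAGES}")
        if "synthgen" in self.stages and self.synth is None:
            raise ValueError("synthgen stage requested but no synth block given")


@dataclass
class RunManifest:
    schema: int = 1
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def record(self, name: str, params: dict, outputs: list, status: str,
               digest: str, elapsed: float) -> None:
        self.stages[name] = {
            "params": params,
            "outputs": [str(p) for p in outputs],
            "inputs_digest": digest,
            "status": status,
            "elapsed_s": round(elapsed, 3),
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"schema": self.schema, "seed": self.seed, "stages": self.stages},
                      fh, indent=2, sort_keys=True)


def _digest(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        if Path(p).exists():
            h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return np.random.default_rng(children[STAGES.index(stage)])


def _state_welch(bundle: SessionBundle, label: str, **kw):
    """Pooled per-window PSDs over all intervals of one behavioural state."""
    fs = bundle.sampling_rate
    segs = []
    freqs = None
    for _, row in bundle.states[bundle.states["state"] == label].iterrows():
        i0, i1 = int(row["start"] * fs), int(row["end"] * fs)
        if i1 - i0 < 2 * defaults.WELCH_NPERSEG:
            continue
        ps = spectral.welch_psd(bundle.lfp[0, i0:i1], fs, **kw)
        segs.append(ps.segments)
        freqs = ps.freqs
    if not segs:
        return None
    segments = np.concatenate(segs, axis=0)
    return spectral.PowerSpectrum(freqs=freqs, power=segments.mean(axis=0),
                                  segments=segments, fs=fs)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _run_synthgen(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    synth_cfg = cfg.synth
    session = generate_session(synth_cfg)
    sess_dir = outdir / "session"
    session.to_dir(sess_dir)
    return sorted(sess_dir.iterdir())


def _run_spectral(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    bundle = SessionBundle.from_dir(outdir / "session")
    out = []
    all_segments = []
    freqs = None
    for label in bundle.states["state"].unique():
        ps = _state_welch(bundle, label)
        if ps is None:
            continue
        model = spectral.fit_spectral_model(ps)
        flat = spectral.flatten(ps, model)
        df = pd.DataFrame({"freq": ps.freqs, "power": ps.power, "flattened": flat})
        path = outdir / f"spectrum_{label}.csv"
        df.to_csv(path, index=False)
        out.append(path)
        mpath = outdir / f"spectral_model_{label}.csv"
        pd.DataFrame(
            [{"offset": model.offset, "exponent": model.exponent,
              "n_peaks": len(model.peaks),
              "peak_centers": ";".join(f"{c:.3f}" for c, _, _ in model.peaks)}]
        ).to_csv(mpath, index=False)
        out.append(mpath)
        all_segments.append(ps.segments)
        freqs = ps.freqs
    if all_segments:
        segments = np.concatenate(all_segments, axis=0)
        if segments.shape[0] >= defaults.N_SORT_BINS:
            smap = spectral.sorted_spectral_map(segments, freqs)
            path = outdir / "sorted_spectral_map.h5"
            with h5py.File(path, "w") as h5:
                h5.create_dataset("matrix", data=smap.matrix)
                h5.create_dataset("freqs", data=smap.freqs)
                h5.create_dataset("sort_keys", data=smap.sort_keys)
            out.append(path)
    return out


def _run_bouts(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    bundle = SessionBundle.from_dir(outdir / "session")
    fs = bundle.sampling_rate
    spec = boutsmod.wavelet_power(bundle.lfp[0], fs)
    theta_a, slope, intercept = boutsmod.fit_background(
        spec, exclude_bands=params.get("exclude_bands", [(3, 10), (20, 35)])
    )
    mask = boutsmod.detect_bouts(spec, theta_a)
    out = []
    rows = []
    for label in bundle.states["state"].unique():
        sel = np.zeros(mask.hits.shape[1], dtype=bool)
        for _, r in bundle.states[bundle.states["state"] == label].iterrows():
            sel[int(r["start"] * fs): int(r["end"] * fs)] = True
        occ = 100.0 * mask.hits[:, sel].mean(axis=1)
        rows.append(pd.DataFrame({"state": label, "freq": mask.freqs, "occupancy_pct": occ}))
    occ_path = outdir / "occupancy.csv"
    pd.concat(rows).to_csv(occ_path, index=False)
    out.append(occ_path)
    for name, band, bw in (
        ("theta", params.get("theta_band", (3, 10)), defaults.KDE_BW_THETA_MS),
        ("gamma", params.get("gamma_band", (20, 35)), defaults.KDE_BW_GAMMA_MS),
    ):
        table = boutsmod.bout_durations(mask, band, label=name, kde_bandwidth_ms=bw)
        path = outdir / f"bouts_{name}.csv"
        table.events.to_csv(path, index=False)
        out.append(path)
    return out


def _run_swr(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    bundle = SessionBundle.from_dir(outdir / "session")
    fs = bundle.sampling_rate
    by_band = {}
    for p in (swrmod.DetectionParams.swr(), swrmod.DetectionParams.high_gamma(),
              swrmod.DetectionParams.hfo()):
        by_band[p.label] = swrmod.detect_events(bundle.lfp[0], bundle.noise_channel, fs, p)
    events = swrmod.label_duplicates(by_band)
    path = outdir / "events.csv"
    swrmod.events_to_frame(events).to_csv(path, index=False)
    return [path]


def _run_crossfreq(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    bundle = SessionBundle.from_dir(outdir / "session")
    fs = bundle.sampling_rate
    rng = _stage_rng(cfg.seed, "crossfreq")
    n_perm = int(params.get("n_permutations", defaults.N_PERMUTATIONS))
    if n_perm < defaults.N_PERMUTATIONS:
        log.warning("running with %d permutations (default %d)", n_perm, defaults.N_PERMUTATIONS)
    ps = spectral.welch_psd(bundle.lfp[0], fs)
    # decimate the frequency grid for the permutation machinery
    comod_df = float(params.get("comod_df", 2.0))
    step = max(1, int(round(comod_df / defaults.SPECTRUM_DF)))
    segs = ps.segments[:, ::step]
    freqs = ps.freqs[::step]
    como, cres = crossfreq.surrogate_cluster_test(segs, freqs, n_perm=n_perm, rng=rng)
    n_surr = int(params.get("n_surrogates", n_perm))
    bic, bres = crossfreq.bicoherence_rednoise_test(
        bundle.lfp[0], fs, n_surrogates=n_surr, rng=rng
    )
    out = []
    path = outdir / "crossfreq.h5"
    with h5py.File(path, "w") as h5:
        h5.create_dataset("comodulogram/freqs", data=como.freqs)
        h5.create_dataset("comodulogram/corr", data=como.corr)
        h5.create_dataset("comodulogram/significant", data=cres.significant)
        h5.create_dataset("bicoherence/f1", data=bic.f1)
        h5.create_dataset("bicoherence/f2", data=bic.f2)
        h5.create_dataset("bicoherence/b", data=bic.b)
        h5.create_dataset("bicoherence/significant", data=bres.significant)
    out.append(path)
    fi, fj = np.where(cres.significant)
    sig = pd.DataFrame({"f_i": como.freqs[fi], "f_j": como.freqs[fj],
                        "corr": como.corr[fi, fj]})
    path = outdir / "comod_significant.csv"
    sig.to_csv(path, index=False)
    out.append(path)
    return out


def _run_spikefield(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    bundle = SessionBundle.from_dir(outdir / "session")
    fs = bundle.sampling_rate
    rng = _stage_rng(cfg.seed, "spikefield")
    n_shuffle = int(params.get("n_shuffles", defaults.N_SPIKE_SHUFFLES))
    n_reassign = int(params.get("n_reassignments", defaults.N_REASSIGNMENTS))
    fmax = min(defaults.SFC_FMAX, fs / 2 - 1)
    freqs = np.arange(defaults.SFC_FMIN, fmax + 0.5, defaults.SFC_DF)
    events_path = outdir / "events.csv"
    swr_times = np.array([])
    if events_path.exists():
        ev = pd.read_csv(events_path)
        swr_times = ev.loc[ev["label"] == "SWR", "peak_s"].to_numpy()
    out = []
    ppc_rows, band_rows = [], []
    for uid, st in sorted(bundle.spikes.items()):
        if len(st) < 10:
            continue
        spec = spikefield.ppc_significance(
            bundle.lfp[0], fs, st, freqs, n_shuffle=n_shuffle, rng=rng
        )
        for f, v, nsp, sg in zip(spec.freqs, spec.ppc, spec.n_spikes, spec.significant):
            ppc_rows.append({"unit": uid, "freq": f, "ppc": v, "n_spikes": nsp,
                             "significant": bool(sg)})
        if swr_times.size:
            cond = spikefield.swr_conditioned_ppc(
                bundle.lfp[0], fs, st, swr_times, freqs,
                n_reassign=n_reassign, rng=rng,
            )
            if cond.excluded:
                band_rows.append({"unit": uid, "excluded": True, "reason": cond.reason})
            else:
                for _, r in cond.band_table.iterrows():
                    band_rows.append({"unit": uid, "excluded": False, "reason": "",
                                      **r.to_dict()})
    path = outdir / "ppc_spectra.csv"
    pd.DataFrame(ppc_rows).to_csv(path, index=False)
    out.append(path)
    path = outdir / "swr_band_tests.csv"
    pd.DataFrame(band_rows).to_csv(path, index=False)
    out.append(path)
    return out


def _run_rhythmicity(cfg: RunConfig, outdir: Path, params: dict) -> list[Path]:
    bundle = SessionBundle.from_dir(outdir / "session")
    rows = []
    for uid, st in sorted(bundle.spikes.items()):
        if len(st) < 2:
            continue
        acg = rhythmicity.autocorrelogram(st)
        fit = rhythmicity.fit_theta_model(acg)
        rows.append({"unit": uid, "n_counts": acg.total_counts, "a": fit.a, "b": fit.b,
                     "c": fit.c, "omega": fit.omega, "tau1": fit.tau1, "tau2": fit.tau2,
                     "theta_index": fit.theta_index, "status": fit.status})
    path = outdir / "theta_fits.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


_STAGE_FUNCS = {
    "synthgen": _run_synthgen,
    "spectral": _run_spectral,
    "bouts": _run_bouts,
    "swr": _run_swr,
    "crossfreq": _run_crossfreq,
    "spikefield": _run_spikefield,
    "rhythmicity": _run_rhythmicity,
}

_DEPENDENCIES = {
    "spectral": ("synthgen",),
    "bouts": ("synthgen",),
    "swr": ("synthgen",),
    "crossfreq": ("synthgen",),
    "spikefield": ("synthgen", "swr"),
    "rhythmicity": ("synthgen",),
}


def run(cfg: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    A stage failure marks downstream dependents as skipped; the manifest
    records the partial state.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed)
    failed: set[str] = set()
    ordered = [s for s in STAGES if s in cfg.stages]
    session_files = list((outdir / "session").glob("*")) if (outdir / "session").exists() else []
    for name in ordered:
        deps = _DEPENDENCIES.get(name, ())
        blocked = [d for d in deps if d in failed]
        if blocked:
            manifest.record(name, cfg.params.get(name, {}), [], f"skipped (failed deps: {blocked})", "", 0.0)
            continue
        t0 = time.perf_counter()
        params = cfg.params.get(name, {})
        try:
            outputs = _STAGE_FUNCS[name](cfg, outdir, params)
            status = "ok"
        except Exception as exc:  # halt downstream dependents, keep manifest
            log.exception("stage %s failed", name)
            outputs, status = [], f"failed: {exc}"
            failed.add(name)
        digest = _digest(session_files or [outdir / "session" / "session.h5"])
        manifest.record(name, params, outputs, status, digest, time.perf_counter() - t0)
        if name == "synthgen":
            session_files = outputs
    manifest.write(outdir / "manifest.json")
    return manifest


def demo_config(outdir: str | Path, seed: int = 0) -> RunConfig:
    """The packaged demonstration run: a 10-minute two-state synthetic session.

    Three units (theta-locked with SWR gain, beta2-locked, unlocked) and
    reduced surrogate counts sized for a desk-scale run; a warning is
    logged where counts fall below the full defaults.
    """
    from .synth import BoutSpec, SwrSpec, UnitSpec

    synth = SynthConfig(
        sampling_rate=1000.0,
        duration=600.0,
        aperiodic_exponent=1.5,
        aperiodic_offset=0.0,
        state_plan=(("search", 0.0, 300.0), ("rest", 300.0, 600.0)),
        bout_specs=(
            BoutSpec(freq=8.0, bandwidth=2.0, rates={"rest": 6.0, "search": 0.5},
                     duration_mean=1.2, duration_sd=0.4, amplitude_sd=2.5, label="theta"),
            BoutSpec(freq=25.0, bandwidth=6.0, rates={"search": 6.0, "rest": 0.5},
                     duration_mean=0.8, duration_sd=0.3, amplitude_sd=2.0, label="beta2"),
        ),
        swr_spec=SwrSpec(rates={"rest": 6.0, "search": 1.0}),
        unit_specs=(
            UnitSpec(base_rate=4.0, locked_freq=8.0, kappa=1.5, swr_gain=3.0),
            UnitSpec(base_rate=6.0, locked_freq=25.0, kappa=1.0),
            UnitSpec(base_rate=3.0),
        ),
        seed=seed,
    )
    return RunConfig(
        outdir=Path(outdir),
        seed=seed,
        synth=synth,
        params={
            "crossfreq": {"n_permutations": 300, "n_surrogates": 100},
            "spikefield": {"n_shuffles": 200, "n_reassignments": 300},
        },
    )
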
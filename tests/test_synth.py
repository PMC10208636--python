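"""Synthetic session generator: spectra, bouts, events, spikes, ground truth."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.special import i0, i1

from ca1osc import synth
from ca1osc.synth import BoutSpec, SwrSpec, SynthConfig, UnitSpec

FS = 1000.0


def _cfg(**kw):
    base = dict(
        sampling_rate=FS,
        duration=300.0,
        aperiodic_exponent=1.5,
        state_plan=(("rest", 0.0, 300.0),),
        seed=0,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestAperiodic:
    def test_white_noise_for_zero_exponent(self):
        x = synth.gen_aperiodic(_cfg(aperiodic_exponent=0.0))
        f, p = sps.welch(x, fs=FS, nperseg=1024)
        sel = (f >= 1) & (f <= 150)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert abs(slope) < 0.05

    @pytest.mark.parametrize("exponent", [1.0, 2.0])
    def test_welch_loglog_slope_matches_exponent(self, exponent):
        x = synth.gen_aperiodic(_cfg(aperiodic_exponent=exponent))
        f, p = sps.welch(x, fs=FS, nperseg=1024)
        sel = (f >= 1) & (f <= 150)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert slope == pytest.approx(-exponent, abs=0.1)

    def test_zero_mean_and_deterministic(self):
        a = synth.gen_aperiodic(_cfg(seed=7))
        b = synth.gen_aperiodic(_cfg(seed=7))
        assert a.mean() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(a, b)

    def test_rejects_invalid_config(self):
        with pytest.raises(ValueError):
            synth.gen_aperiodic(_cfg(aperiodic_exponent=np.nan))
        with pytest.raises(ValueError):
            synth.gen_aperiodic(_cfg(aperiodic_exponent=-1.0))
        with pytest.raises(ValueError):
            _cfg(duration=1.0).validate()  # too few samples


class TestConfigValidation:
    def test_overlapping_states_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _cfg(state_plan=(("rest", 0.0, 200.0), ("search", 100.0, 300.0))).validate()

    def test_state_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            _cfg(state_plan=(("rest", 0.0, 400.0),)).validate()

    def test_sampling_rate_floor(self):
        with pytest.raises(ValueError, match="4x"):
            _cfg(bout_specs=(BoutSpec(freq=400.0, rates={"rest": 1.0}),)).validate()

    def test_locked_freq_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            _cfg(unit_specs=(UnitSpec(base_rate=1.0, locked_freq=600.0, kappa=1.0),)).validate()


class TestBouts:
    two_state = (("search", 0.0, 300.0), ("rest", 300.0, 600.0))

    def test_zero_rate_state_has_no_bouts(self):
        cfg = _cfg(
            duration=600.0,
            state_plan=self.two_state,
            bout_specs=(BoutSpec(freq=8.0, rates={"rest": 6.0, "search": 0.0}, label="theta"),),
        )
        _, truth, _ = synth.gen_bouts(cfg, background_sd=1.0)
        assert (truth["state"] == "rest").all()

    def test_state_dependent_occupancy(self):
        cfg = _cfg(
            duration=600.0,
            state_plan=self.two_state,
            bout_specs=(BoutSpec(freq=8.0, rates={"rest": 6.0, "search": 0.5}, label="theta"),),
            seed=3,
        )
        _, truth, _ = synth.gen_bouts(cfg, background_sd=1.0)
        occ_rest = synth.truth_occupancy(truth, "theta", [(300.0, 600.0)])
        occ_search = synth.truth_occupancy(truth, "theta", [(0.0, 300.0)])
        assert occ_rest > occ_search

    def test_bouts_confined_to_state_and_tapered(self):
        cfg = _cfg(
            duration=600.0,
            state_plan=self.two_state,
            bout_specs=(BoutSpec(freq=8.0, rates={"rest": 6.0}, duration_mean=2.0,
                                 duration_sd=1.5, label="theta"),),
            seed=5,
        )
        sig, truth, _ = synth.gen_bouts(cfg, background_sd=1.0)
        assert (truth["start"] >= 300.0).all() and (truth["end"] <= 600.0).all()
        # taper reaches zero at edges: signal is exactly 0 outside bouts
        outside = np.ones(int(600 * FS), dtype=bool)
        for _, r in truth.iterrows():
            outside[int(r["start"] * FS): int(r["end"] * FS)] = False
        assert np.abs(sig[outside]).max() == 0.0

    def test_injected_bout_envelope_exceeds_background(self):
        """Filter-and-measure: 1 s, 8 Hz, 4 SD bout -> 7-9 Hz envelope peak > 3 SD."""
        cfg = _cfg(seed=2)
        bg = synth.gen_aperiodic(cfg)
        sd = bg.std()
        n = len(bg)
        t = np.arange(int(1.0 * FS)) / FS
        bout = 4.0 * sd * np.hanning(len(t)) * np.cos(2 * np.pi * 8.0 * t)
        x = bg.copy()
        x[n // 2: n // 2 + len(t)] += bout
        sos = sps.butter(4, (7, 9), btype="bandpass", fs=FS, output="sos")
        env = np.abs(sps.hilbert(sps.sosfiltfilt(sos, x)))
        env_bg = np.abs(sps.hilbert(sps.sosfiltfilt(sos, bg)))
        assert env[n // 2: n // 2 + len(t)].max() > 3 * env_bg.std()

    def test_truncation_recorded(self):
        cfg = _cfg(
            duration=600.0,
            state_plan=self.two_state,
            bout_specs=(BoutSpec(freq=8.0, rates={"rest": 6.0}, duration_mean=30.0,
                                 duration_sd=20.0, label="theta"),),
            seed=1,
        )
        _, truth, _ = synth.gen_bouts(cfg, background_sd=1.0)
        assert truth["truncated"].any()
        assert (truth["end"] <= 600.0).all()


class TestSwrs:
    def test_zero_rate_empty(self):
        cfg = _cfg(swr_spec=SwrSpec(rates={"rest": 0.0}))
        bg = synth.gen_aperiodic(cfg)
        sig, truth = synth.gen_swrs(cfg, bg)
        assert len(truth) == 0
        assert np.abs(sig).max() == 0.0

    def test_events_recorded_and_nonoverlapping(self):
        cfg = _cfg(duration=600.0, state_plan=(("rest", 0.0, 600.0),),
                   swr_spec=SwrSpec(rates={"rest": 10.0}), seed=9)
        bg = synth.gen_aperiodic(cfg)
        _, truth = synth.gen_swrs(cfg, bg)
        assert len(truth) > 50
        assert (truth["start"] < truth["peak"]).all()
        assert (truth["peak"] < truth["end"]).all()
        starts = truth["start"].to_numpy()
        ends = truth["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()


class TestSpikes:
    def test_rate_conservation_homogeneous(self):
        cfg = _cfg(unit_specs=(UnitSpec(base_rate=5.0),), seed=11)
        spikes = synth.gen_spikes(cfg, {}, synth.generate_session(_cfg()).truth_swrs)
        n = len(spikes[0])
        expect = 5.0 * 300.0
        assert abs(n - expect) < 3 * np.sqrt(expect)

    def test_von_mises_locking_matches_analytic_ppc(self):
        """kappa=2 locking: brute-force pairwise cos of phase diffs ~ (I1/I0)^2."""
        cfg = _cfg(unit_specs=(UnitSpec(base_rate=4.0, locked_freq=8.0, kappa=2.0),), seed=13)
        t = np.arange(int(300.0 * FS)) / FS
        tracks = {8.0: 2 * np.pi * 8.0 * t}
        spikes = synth.gen_spikes(cfg, tracks, synth.generate_session(_cfg()).truth_swrs)
        ph = np.mod(tracks[8.0][(spikes[0] * FS).astype(int)] + np.pi, 2 * np.pi) - np.pi
        z = np.exp(1j * ph)
        n = len(ph)
        ppc_bf = (np.abs(z.sum()) ** 2 - n) / (n * (n - 1))
        expect = (i1(2.0) / i0(2.0)) ** 2
        assert ppc_bf == pytest.approx(expect, abs=0.05)

    def test_unlocked_unit_has_no_phase_preference(self):
        cfg = _cfg(unit_specs=(UnitSpec(base_rate=4.0, kappa=0.0),), seed=14)
        t = np.arange(int(300.0 * FS)) / FS
        tracks = {8.0: 2 * np.pi * 8.0 * t}
        spikes = synth.gen_spikes(cfg, tracks, synth.generate_session(_cfg()).truth_swrs)
        ph = tracks[8.0][(spikes[0] * FS).astype(int)]
        z = np.exp(1j * ph)
        n = len(ph)
        ppc = (np.abs(z.sum()) ** 2 - n) / (n * (n - 1))
        assert abs(ppc) < 3.0 / np.sqrt(n * (n - 1) / 2)

    def test_swr_gain_multiplies_rate_in_windows(self):
        cfg = _cfg(
            duration=600.0,
            state_plan=(("rest", 0.0, 600.0),),
            swr_spec=SwrSpec(rates={"rest": 6.0}),
            unit_specs=(UnitSpec(base_rate=4.0, swr_gain=5.0),),
            seed=15,
        )
        bundle = synth.generate_session(cfg)
        spikes = bundle.spikes[0]
        mask_dur = 0.0
        n_in = 0
        for _, r in bundle.truth_swrs.iterrows():
            a, b = r["peak"] - 0.3, r["peak"] + 0.3
            mask_dur += 0.6
            n_in += ((spikes >= a) & (spikes < b)).sum()
        rate_in = n_in / mask_dur
        rate_out = (len(spikes) - n_in) / (600.0 - mask_dur)
        assert rate_in / rate_out == pytest.approx(5.0, rel=0.25)


class TestBundle:
    def test_determinism_bit_identical(self):
        cfg = _cfg(
            duration=60.0,
            state_plan=(("rest", 0.0, 60.0),),
            bout_specs=(BoutSpec(freq=8.0, rates={"rest": 4.0}, label="theta"),),
            swr_spec=SwrSpec(rates={"rest": 4.0}),
            unit_specs=(UnitSpec(base_rate=5.0, locked_freq=8.0, kappa=1.0),),
            seed=21,
        )
        a, b = synth.generate_session(cfg), synth.generate_session(cfg)
        np.testing.assert_array_equal(a.lfp, b.lfp)
        np.testing.assert_array_equal(a.noise_channel, b.noise_channel)
        np.testing.assert_array_equal(a.spikes[0], b.spikes[0])
        assert a.truth_bouts.equals(b.truth_bouts)
        assert a.truth_swrs.equals(b.truth_swrs)

    def test_invariants_and_roundtrip(self, tmp_path):
        cfg = _cfg(
            duration=60.0,
            state_plan=(("rest", 0.0, 60.0),),
            bout_specs=(BoutSpec(freq=8.0, rates={"rest": 4.0}, label="theta"),),
            unit_specs=(UnitSpec(base_rate=5.0),),
            seed=22,
        )
        bundle = synth.generate_session(cfg)
        assert np.isfinite(bundle.lfp).all()
        assert (bundle.spikes[0] > 0).all() and (bundle.spikes[0] < 60.0).all()
        bundle.to_dir(tmp_path / "sess")
        back = synth.SessionBundle.from_dir(tmp_path / "sess")
        np.testing.assert_allclose(back.lfp, bundle.lfp)
        np.testing.assert_allclose(back.spikes[0], bundle.spikes[0])
        assert back.config.seed == cfg.seed

    def test_truth_occupancy_merges_overlaps(self):
        import pandas as pd

        truth = pd.DataFrame(
            {"band": ["theta"] * 2, "start": [10.0, 10.5], "end": [11.0, 11.5]}
        )
        occ = synth.truth_occupancy(truth, "theta", [(0.0, 100.0)])
        assert occ == pytest.approx(1.5, rel=1e-6)
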
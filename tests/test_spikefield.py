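"""Spike-field coherence: phases, PPC, significance, SWR-conditioned split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps
from scipy.special import i0, i1

from ca1osc import spikefield, synth

FS = 1000.0


class TestSpikePhases:
    def test_peak_locked_spikes_zero_phase(self):
        t = np.arange(int(60 * FS)) / FS
        lfp = np.cos(2 * np.pi * 8.0 * t)
        spikes = np.arange(5.0, 55.0, 0.125)  # cosine peaks
        pset = spikefield.spike_phases(lfp, FS, spikes, freqs=np.array([8.0]))
        ph = pset.phases[np.isfinite(pset.phases[:, 0]), 0]
        resultant = np.exp(1j * ph).mean()
        assert abs(np.angle(resultant)) < 0.05
        assert np.sqrt(-2 * np.log(np.abs(resultant))) < 0.05  # circular SD

    def test_rising_zero_crossing_quadrature(self):
        t = np.arange(int(60 * FS)) / FS
        lfp = np.cos(2 * np.pi * 8.0 * t)
        # rising zero crossings of cos at phase -pi/2, i.e. t = -1/32 mod 1/8
        spikes = np.arange(5.0, 55.0, 0.125) - 1 / 32
        pset = spikefield.spike_phases(lfp, FS, spikes, freqs=np.array([8.0]))
        ph = pset.phases[np.isfinite(pset.phases[:, 0]), 0]
        assert np.angle(np.exp(1j * ph).mean()) == pytest.approx(-np.pi / 2, abs=0.05)

    def test_agrees_with_hilbert_oracle(self):
        """Windowed Fourier phase vs Hilbert phase of the bandpassed signal."""
        rng = np.random.default_rng(0)
        n = int(120 * FS)
        coef = np.fft.rfft(rng.standard_normal(n))
        fr = np.fft.rfftfreq(n, 1 / FS)
        lfp = np.fft.irfft(coef * np.exp(-((fr - 8.0) ** 2) / (2 * 0.5 ** 2)), n=n)  # narrowband at 8
        spikes = rng.uniform(5, 115, 300)
        pset = spikefield.spike_phases(lfp, FS, spikes, freqs=np.array([8.0]))
        sos = sps.butter(3, (7, 9), btype="bandpass", fs=FS, output="sos")
        hphase = np.angle(sps.hilbert(sps.sosfiltfilt(sos, lfp)))
        idx = np.round(spikes * FS).astype(int)
        ok = np.isfinite(pset.phases[:, 0])
        diff = np.angle(np.exp(1j * (pset.phases[ok, 0] - hphase[idx[ok]])))
        # circular RMSE after removing any constant offset
        diff = np.angle(np.exp(1j * (diff - np.angle(np.exp(1j * diff).mean()))))
        assert np.sqrt((diff ** 2).mean()) < 0.2

    def test_edge_spikes_excluded(self):
        lfp = np.zeros(int(10 * FS))
        spikes = np.array([0.1, 5.0, 9.9])
        pset = spikefield.spike_phases(lfp, FS, spikes, freqs=np.array([2.0]))
        # 5 cycles at 2 Hz = 2.5 s window: edge spikes have no valid phase
        assert not np.isfinite(pset.phases[0, 0])
        assert not np.isfinite(pset.phases[2, 0])


class TestPPC:
    def test_all_identical_phases(self):
        assert spikefield.ppc(np.full(17, 0.7)) == pytest.approx(1.0)

    def test_four_quadrature_phases(self):
        """Brute force over the 6 unordered pairs gives -1/3."""
        assert spikefield.ppc(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])) == pytest.approx(-1 / 3)

    def test_undefined_below_two_spikes(self):
        with pytest.raises(ValueError):
            spikefield.ppc(np.array([0.5]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=60))
    def test_closed_form_equals_bruteforce(self, phases):
        ph = np.array(phases)
        brute = np.mean([np.cos(a - b) for i, a in enumerate(ph) for b in ph[i + 1:]])
        assert spikefield.ppc(ph) == pytest.approx(brute, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=3, max_size=40),
           st.integers(0, 39))
    def test_phase_wrap_invariance(self, phases, which):
        ph = np.array(phases)
        shifted = ph.copy()
        shifted[which % len(ph)] += 2 * np.pi
        assert spikefield.ppc(shifted) == pytest.approx(spikefield.ppc(ph), abs=1e-9)

    def test_von_mises_sample_matches_analytic(self):
        rng = np.random.default_rng(1)
        vals = [spikefield.ppc(rng.vonmises(0.0, 2.0, 500)) for _ in range(100)]
        expect = (i1(2.0) / i0(2.0)) ** 2
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 3 * se

    def test_nan_aware_matrix_form(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(-np.pi, np.pi, size=(40, 3))
        phases[:30, 2] = np.nan
        vals, counts = spikefield.ppc_from_phases(phases)
        assert counts[2] == 10
        assert vals[0] == pytest.approx(spikefield.ppc(phases[:, 0]))
        assert vals[2] == pytest.approx(spikefield.ppc(phases[:, 2]))


class TestPPCSignificance:
    freqs = np.arange(2.0, 41.0)

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            spikefield.ppc_significance(np.zeros(4096), FS, np.array([1.0, 2.0]),
                                        n_shuffle=0)

    def test_locked_unit_significant_near_target(self, theta_session):
        spec = spikefield.ppc_significance(
            theta_session.lfp[0], FS, theta_session.spikes[0], self.freqs,
            n_shuffle=200, rng=np.random.default_rng(3),
        )
        near8 = (self.freqs >= 7) & (self.freqs <= 9)
        assert spec.significant[near8].any()
        i8 = np.argmin(np.abs(self.freqs - 8))
        assert spec.ppc[i8] > 0.2

    def test_poisson_units_on_noise_lfp_not_significant(self):
        """False-positive control: homogeneous Poisson spikes on pure-noise LFP."""
        cfg = synth.SynthConfig(duration=300.0, aperiodic_exponent=1.5,
                                state_plan=(("rest", 0.0, 300.0),), seed=47)
        lfp = synth.gen_aperiodic(cfg)
        rng = np.random.default_rng(4)
        fracs = []
        for _ in range(3):
            spikes = np.sort(rng.uniform(0, 300.0, 900))
            spec = spikefield.ppc_significance(lfp, FS, spikes, self.freqs,
                                               n_shuffle=200, rng=rng)
            fracs.append(spec.significant.mean())
        assert np.mean(fracs) <= 0.05

    def test_rayleigh_uniform_vs_concentrated(self):
        rng = np.random.default_rng(5)
        assert spikefield.rayleigh_p(rng.uniform(-np.pi, np.pi, 500)) > 0.01
        assert spikefield.rayleigh_p(rng.vonmises(0, 2.0, 500)) < 1e-6


class TestPreferredFrequency:
    def _spec(self, freqs, sig_mask, ppc):
        return spikefield.PPCSpectrum(freqs=freqs, ppc=ppc, n_spikes=np.full(len(freqs), 100.0),
                                      significant=sig_mask)

    def test_unimodal(self):
        freqs = np.arange(2.0, 41.0)
        specs = []
        for _ in range(20):
            sig = np.abs(freqs - 8) <= 1
            ppc = np.where(sig, 0.3, 0.01)
            specs.append(self._spec(freqs, sig, ppc))
        out = spikefield.preferred_frequency_distribution(specs, grid=np.arange(2.0, 41.0, 0.5))
        assert out["grid"][np.argmax(out["density_significant"])] == pytest.approx(8.0, abs=1.0)

    def test_bimodal_equal_mass(self):
        freqs = np.arange(2.0, 41.0)
        specs = []
        for k in range(40):
            center = 8.0 if k % 2 == 0 else 30.0
            sig = np.abs(freqs - center) <= 1
            specs.append(self._spec(freqs, sig, np.where(sig, 0.3, 0.01)))
        # evaluate beyond the sampled range so neither mode's KDE tail is cut
        grid = np.arange(-12.0, 53.0, 0.25)
        out = spikefield.preferred_frequency_distribution(specs, grid=grid)
        dens = out["density_significant"]
        m1 = np.trapezoid(dens[grid <= 19], grid[grid <= 19])
        m2 = np.trapezoid(dens[grid > 19], grid[grid > 19])
        assert abs(m1 - m2) < 0.02 * (m1 + m2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spikefield.preferred_frequency_distribution([])


class TestSWRConditioned:
    freqs = np.arange(2.0, 201.0)

    def test_swr_locked_unit_low_band_positive(self, swr_session):
        cond = spikefield.swr_conditioned_ppc(
            swr_session.lfp[0], FS, swr_session.spikes[0],
            swr_session.truth_swrs["peak"].to_numpy(), self.freqs,
            n_reassign=500, rng=np.random.default_rng(6),
        )
        assert not cond.excluded
        row = cond.band_table[(cond.band_table["band_lo"] == 4)].iloc[0]
        assert row["significant"]
        assert row["delta"] > 0

    def test_partition_exhaustive_and_disjoint(self, swr_session):
        cond = spikefield.swr_conditioned_ppc(
            swr_session.lfp[0], FS, swr_session.spikes[0],
            swr_session.truth_swrs["peak"].to_numpy(), self.freqs,
            n_reassign=50, rng=np.random.default_rng(7),
        )
        # counts cover every interior spike exactly once
        windows = spikefield.merge_windows(swr_session.truth_swrs["peak"].to_numpy(), 0.6)
        spikes = swr_session.spikes[0]
        half = int(round(5 * FS / self.freqs.min() / 2))
        interior = (np.round(spikes * FS) >= half) & (np.round(spikes * FS) < len(swr_session.lfp[0]) - half)
        assert cond.n_swr_spikes + cond.n_residual_spikes == interior.sum()

    def test_too_few_swr_spikes_excluded(self):
        rng = np.random.default_rng(8)
        lfp = rng.standard_normal(int(60 * FS))
        spikes = np.sort(rng.uniform(5, 55, 200))
        cond = spikefield.swr_conditioned_ppc(lfp, FS, spikes, np.array([30.0]),
                                              self.freqs, n_reassign=50, rng=rng)
        assert cond.excluded
        assert "minimum" in cond.reason

    def test_all_spikes_inside_windows_excluded(self):
        rng = np.random.default_rng(9)
        lfp = rng.standard_normal(int(60 * FS))
        spikes = np.sort(rng.uniform(29.8, 30.2, 50))  # all within one window
        cond = spikefield.swr_conditioned_ppc(lfp, FS, spikes, np.array([30.0]),
                                              self.freqs, n_reassign=50, rng=rng)
        assert cond.excluded
        assert "residual" in cond.reason


def test_merge_windows_overlap():
    out = spikefield.merge_windows(np.array([10.0, 10.4, 20.0]), 0.6)
    np.testing.assert_allclose(out, [(9.7, 10.7), (19.7, 20.3)])
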
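import numpy as np
import pytest

from ca1osc import synth

FS = 1000.0


@pytest.fixture(scope="session")
def theta_session():
    """300 s session with continuous 8 Hz theta and a locked unit.

    Used by spike-field tests: unit 0 locks at 8 Hz with kappa = 2, unit 1
    is homogeneous Poisson.  The oscillation runs through the whole
    recording so spike phases are well defined everywhere.
    """
    cfg = synth.SynthConfig(
        duration=300.0,
        aperiodic_exponent=1.5,
        state_plan=(("rest", 0.0, 300.0),),
        unit_specs=(
            synth.UnitSpec(base_rate=3.0, locked_freq=8.0, kappa=2.0),
            synth.UnitSpec(base_rate=3.0),
        ),
        seed=42,
    )
    bundle = synth.generate_session(cfg)
    t = np.arange(bundle.lfp.shape[1]) / cfg.sampling_rate
    track = 2 * np.pi * 8.0 * t
    bundle.lfp = bundle.lfp + 3.0 * bundle.lfp[0].std() * np.cos(track)
    bundle.phase_tracks = {8.0: track}
    bundle.spikes = synth.gen_spikes(
        cfg, bundle.phase_tracks, bundle.truth_swrs,
        rng=np.random.default_rng(4242),
    )
    return bundle


@pytest.fixture(scope="session")
def swr_session():
    """600 s rest session with SWRs and a unit locked at 6 Hz only inside them."""
    cfg = synth.SynthConfig(
        duration=600.0,
        aperiodic_exponent=1.5,
        state_plan=(("rest", 0.0, 600.0),),
        swr_spec=synth.SwrSpec(rates={"rest": 8.0}),
        unit_specs=(
            synth.UnitSpec(base_rate=3.0, locked_freq=6.0, kappa=3.0,
                           swr_gain=3.0, lock_in_swr_only=True),
        ),
        seed=43,
    )
    return synth.generate_session(cfg)
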
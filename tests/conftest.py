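"""Shared fixtures: simulated lineages and extracted cycle tables.

Everything is generated at test time from seeded simulations; session
scope keeps the suite fast by reusing the expensive artifacts.
"""

import numpy as np
import pytest

import oricycle as oc


_OBS_FIELDS = {"frame_interval", "length_noise_cv", "spot_detect_prob",
               "merge_radius", "position_jitter_sd"}


def simulate_and_extract(variant, n_lineages, sim_seed, obs_seed,
                         duration=1800.0, **overrides):
    """Simulate -> render -> extract -> QC for one model variant.

    Keyword overrides are routed to the model parameters or to the
    observation model by field name.
    """
    params = oc.default_params(variant)
    obs = oc.ObsConfig(seed=obs_seed)
    for key, value in overrides.items():
        if key in _OBS_FIELDS:
            setattr(obs, key, value)
        else:
            assert hasattr(params, key), key
            setattr(params, key, value)
    config = oc.SimConfig(n_lineages=n_lineages, duration=duration,
                          seed=sim_seed)
    logs = oc.simulate_lineages(params, config)
    frames = oc.render_frames(logs, obs)
    division, _ = oc.qc_filter(oc.build_division_cycles(frames))
    replication, _ = oc.qc_filter(oc.build_replication_cycles(frames))
    return logs, frames, division, replication


@pytest.fixture(scope="session")
def da_logs():
    """Double-adder lineages at the default slow-growth conditions."""
    params = oc.default_params("double_adder")
    config = oc.SimConfig(n_lineages=200, duration=1800.0, seed=101)
    return oc.simulate_lineages(params, config)


@pytest.fixture(scope="session")
def da_frames(da_logs):
    return oc.render_frames(da_logs, oc.ObsConfig(seed=103))


@pytest.fixture(scope="session")
def da_tables(da_frames):
    """QC-filtered division- and replication-centric tables."""
    division, _ = oc.qc_filter(oc.build_division_cycles(da_frames))
    replication, _ = oc.qc_filter(oc.build_replication_cycles(da_frames))
    return division, replication


@pytest.fixture(scope="session")
def da_true_tables(da_logs):
    """Exact (event-log) cycle tables for the same lineages."""
    return (
        oc.true_division_cycles(da_logs),
        oc.true_replication_cycles(da_logs),
    )


@pytest.fixture(scope="session")
def noiseless_frames():
    """Noise-free rendering of a smaller double-adder run."""
    params = oc.default_params("double_adder")
    config = oc.SimConfig(n_lineages=40, duration=1800.0, seed=107)
    logs = oc.simulate_lineages(params, config)
    obs = oc.ObsConfig(length_noise_cv=0.0, spot_detect_prob=1.0,
                       merge_radius=0.0, position_jitter_sd=0.0, seed=0)
    return logs, oc.render_frames(logs, obs)


@pytest.fixture(scope="session")
def variant_tables():
    """Extracted tables for the three competing control models."""
    out = {}
    # the sizer's Li-Lb null is a tight call (initiation-inheritance
    # selection leaves a small real correlation), so it gets more lineages
    sizes = {"initiation_timer": 100, "initiation_sizer": 200,
             "independent_adders": 100}
    for i, variant in enumerate(sizes):
        _, _, division, replication = simulate_and_extract(
            variant, n_lineages=sizes[variant],
            sim_seed=211 + i, obs_seed=311 + i
        )
        out[variant] = (division, replication)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
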
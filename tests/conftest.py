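"""Shared fixtures: small synthetic experiments generated at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from respirotraits.config import RunConfig, SimConfig


def small_sim_config(**overrides) -> SimConfig:
    """One batch of 4 chambers at coarse sampling: fast but full-structure."""
    defaults = dict(
        n_batches=1,
        chambers_per_batch=4,
        group_pattern=(4,),
        sample_interval_s=5.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    """A 4-fish, two-trial experiment (coarse 5 s sampling), simulated once."""
    from respirotraits import synth

    cfg = small_sim_config()
    data = synth.simulate_experiment(cfg)
    raw = pd.concat(
        [
            data["raw_initial"].assign(trial="initial"),
            data["raw_final"].assign(trial="final"),
        ],
        ignore_index=True,
    )
    return {"config": cfg, "raw": raw, **data}


@pytest.fixture(scope="session")
def small_estimates(small_experiment):
    from respirotraits import core

    return core.process_experiment(
        small_experiment["raw"],
        small_experiment["schedule"],
        small_experiment["metadata"],
        chamber_volume_l=small_experiment["config"].chamber_volume_l,
    )


@pytest.fixture(scope="session")
def noiseless_trace():
    """Single chamber, no noise, no bursts, constant background: exact slopes."""
    from respirotraits import synth

    cfg = small_sim_config(
        chambers_per_batch=1,
        group_pattern=(1,),
        noise_sd=0.0,
        burst_rate_per_h=0.0,
        background_start=-0.05,
        background_end=-0.05,
        day_activity_multiplier=1.0,
        shelter_multiplier=1.0,
        day2_multiplier=1.0,
        trial_duration_h=10.0,
        condition_change_offset_h=5.0,
        chase_offset_h=9.0,
        sample_interval_s=1.0,
        seed=3,
    )
    rng = np.random.default_rng(cfg.seed)
    fish = synth.simulate_cohort(cfg, rng)
    traces, sched = synth.simulate_trial(fish, cfg, "initial", rng)
    return {"config": cfg, "fish": fish[0], "trace": traces, "schedule": sched}
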
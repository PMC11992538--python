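import numpy as np
import pytest

from focalenergy import simulate as sim
from focalenergy.ethogram import (
    Bout,
    EnvironmentRecord,
    FocalSample,
    ForagingOutcome,
)


def make_sample(
    bout_spec,
    sample_id="s1",
    site="TestRiver",
    success=0,
    failure=0,
    **env,
):
    """Build a FocalSample from [(behavior, duration), ...]."""
    bouts = tuple(
        Bout(behavior=b, duration=d, index=i)
        for i, (b, d) in enumerate(bout_spec)
    )
    return FocalSample(
        sample_id=sample_id,
        site=site,
        bouts=bouts,
        outcome=ForagingOutcome(success_count=success, failure_count=failure),
        environment=EnvironmentRecord(**env),
    )


@pytest.fixture
def toy_sample():
    """300-s sample: diving 120, eye-submerging 30, swimming 90, vigilance 45,
    feeding 15 (40/10/30/15/5 percent)."""
    return make_sample(
        [
            ("diving", 120.0),
            ("eye_submerging", 30.0),
            ("swimming", 90.0),
            ("vigilance", 45.0),
            ("feeding", 15.0),
        ],
        success=2,
        failure=0,
        avg_fish_weight_g=2.5,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default three-site simulated dataset (87 samples), shared across tests."""
    cfg = sim.default_config(seed=20240)
    samples, truth = sim.simulate_dataset(cfg)
    return samples, truth


def single_site_config(n_samples, seed, weight_effects=(), success_effects=(),
                       site_name="Shuaishui"):
    """One-site config derived from the default profile of ``site_name``."""
    base = sim.default_config(seed=0).sites[site_name]
    site = sim.SiteConfig(
        n_samples=n_samples,
        duration_mean_s=base.duration_mean_s,
        duration_sd_s=base.duration_sd_s,
        bout_frequency=base.bout_frequency,
        mean_bout_s=base.mean_bout_s,
        p_success=base.p_success,
        covariates=base.covariates,
    )
    return sim.SimConfig(
        sites={site_name: site},
        weight_effects=tuple(weight_effects),
        success_effects=tuple(success_effects),
        seed=seed,
    )
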
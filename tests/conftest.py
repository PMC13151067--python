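import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from macropan.schema import acrk_10mer_schema, camcbt_12mer_schema
from macropan.simulate import RoundSpec, default_config, run_campaign


@pytest.fixture(scope="session")
def schema_10mer():
    return acrk_10mer_schema()


@pytest.fixture(scope="session")
def schema_12mer():
    return camcbt_12mer_schema()


def small_config(seed=0, n_clones=300, depth=2000, **overrides):
    """Scaled-down campaign for fast unit tests (latent dynamics identical
    to the defaults; only pool size and sequencing depth shrink)."""
    cfg = default_config(seed=seed, n_clones=n_clones, **overrides)
    for rounds in cfg.campaigns.values():
        for i, spec in enumerate(rounds):
            rounds[i] = RoundSpec(**{**spec.__dict__, "depth": depth})
    return cfg


@pytest.fixture(scope="session")
def small_campaign():
    """One shared small campaign (counts mode) for analytics tests."""
    cfg = small_config(seed=11, n_clones=500, depth=20000)
    return run_campaign(cfg, emit="counts")


def single_vs_alternating_campaigns(depth=100_000):
    """Two-strategy design mirroring a streptavidin-only selection run in
    parallel with a resin-alternating one."""
    plans = {
        "strep_only": ["streptavidin"] * 4,
        "strep_nhs": ["streptavidin", "NHS", "streptavidin", "NHS"],
    }
    i5 = ["AGCGTAGC", "CCTGAGAT"]
    i7 = ["TCGCCTTA", "CTAGTACG", "TTCTGCCT", "GCTCAGGA"]
    target = [10.0, 5.0, 2.0, 1.0]
    washes = [8, 8, 10, 10]
    return {
        strategy: [
            RoundSpec(strategy, r + 1, resins[r], target[r], washes[r], True, depth, i5[i], i7[r])
            for r in range(4)
        ]
        for i, (strategy, resins) in enumerate(plans.items())
    }
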
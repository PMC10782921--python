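import numpy as np
import pytest
from hypothesis import settings

from silencerein.simulate import FixtureSpec, generate_fixture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small planted dataset shared across fast tests: one 600-kb
    chromosome, 300 anchor sites, 2-SD silencer effects."""
    out = tmp_path_factory.mktemp("fixture_small")
    spec = FixtureSpec(
        n_chroms=1,
        chrom_length=600_000,
        n_loops=400,
        n_anchor_sites=300,
        n_silencers=40,
        n_non_silencers=15,
        n_enhancers=15,
        n_promoters=100,
        seed=1,
    )
    generate_fixture(spec, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
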
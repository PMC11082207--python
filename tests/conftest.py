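import pytest

from revscreen import fixtures, pipeline


@pytest.fixture(scope="session")
def small_universe():
    """A compact planted universe shared by data/validation tests."""
    spec = fixtures.FixtureSpec(n_targets=4, actives_per_target=6,
                                heldout_per_target=2, n_decoys=12, seed=5)
    training, test = fixtures.generate_universe(spec)
    return spec, training, test


@pytest.fixture(scope="session")
def default_study():
    """The default planted reverse-screening study: 20 targets, 30 actives
    each, 5 held-out analogs per target, fixed seed."""
    spec = fixtures.FixtureSpec(seed=7)
    return pipeline.run_planted_study(spec, n_conformers=3, seed=7,
                                      cutoffs=(1, 5, 15))
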
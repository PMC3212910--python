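import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from tisskit import synth  # noqa: E402


@pytest.fixture(scope="session")
def context():
    """(repository, flattened operational templates) for the plain-RM set."""
    return synth.default_context(1)


@pytest.fixture(scope="session")
def repo(context):
    return context[0]


@pytest.fixture(scope="session")
def opts(context):
    return context[1]


@pytest.fixture()
def rng():
    return random.Random(20260922)


def make_composition(template: str, seed: int = 1, **kw):
    repo, opts = synth.default_context(1)
    cfg = synth.GeneratorConfig(seed=seed, template=template, **kw)
    return synth.generate_composition(cfg, repo, opts)


@pytest.fixture()
def admission_claim():
    return make_composition("admission_claim", with_original_submission=True)


@pytest.fixture()
def authorization_comp():
    return make_composition("tests_procedures_authorization")
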
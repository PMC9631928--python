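import pytest
from hypothesis import HealthCheck, settings

import admeta

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_table():
    return admeta.load_fixture()


@pytest.fixture()
def allele_effects():
    """Per-study allele-model effects from a cohort table, drops excluded."""

    def _effects(table, **kwargs):
        out = []
        for s in table:
            if not s.has_genotypes:
                continue
            est = admeta.odds_ratio(
                admeta.build_contrast(s, "allele", **kwargs), study_id=s.study_id
            )
            if not est.is_dropped:
                out.append(est)
        return out

    return _effects
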
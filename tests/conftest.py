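import pandas as pd
import pytest

from hydrascore import (
    GeneratorConfig,
    build_features,
    classify_cohort,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(n_participants=200, seed=11))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return build_features(
        default_cohort.voids, default_cohort.assessments, default_cohort.bodymass
    )


@pytest.fixture(scope="session")
def default_classified(default_features):
    classified, incomplete = classify_cohort(default_features)
    assert len(incomplete) == 0
    return classified


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return generate_cohort(GeneratorConfig.zero_noise(n_participants=120, seed=7))


@pytest.fixture(scope="session")
def zero_noise_classified(zero_noise_cohort):
    feats = build_features(zero_noise_cohort.voids, zero_noise_cohort.assessments)
    classified, _ = classify_cohort(feats)
    return classified


def make_voids(pid: str, hours, volumes, usgs, t0="2024-06-01 08:00:00") -> pd.DataFrame:
    base = pd.Timestamp(t0)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "time": [base + pd.Timedelta(hours=float(h)) for h in hours],
            "volume": list(volumes),
            "usg": list(usgs),
        }
    )
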
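import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def separable_records():
    """A small, well-separated three-class study (4 ears/class x 25 A-scans)."""
    import earoct as eo
    from earoct.classify import extract_dataset_features

    specs = eo.study_specs(4, 25, snr_db=80.0, rng_seed=0)
    return extract_dataset_features(eo.make_dataset(specs, rng_seed=0))


@pytest.fixture(scope="session")
def trained_model(separable_records):
    from earoct.classify import train_classifier

    return train_classifier(
        [r.features for r in separable_records],
        [r.label for r in separable_records],
        rng_seed=7,
    )
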
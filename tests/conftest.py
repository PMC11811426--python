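import numpy as np
import pytest

from mmdepnet.synthetic import GeneratorConfig, SubjectRecord, generate_corpus


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_generator_config():
    """A very small corpus configuration for structural tests."""
    return GeneratorConfig(n_subjects=10, prevalence=0.5, effect_size=2.0,
                           frames_per_clip=6, frame_size=(32, 32),
                           clip_seconds=0.5, seed=42)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_generator_config, tmp_path_factory):
    """Generated corpus on disk: (directory, manifest)."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = generate_corpus(tiny_generator_config, out)
    return out, manifest


def make_record(label=0, phq8=None, subject_id="S0000", sex="female"):
    if phq8 is None:
        phq8 = 20 if label else 4
    return SubjectRecord(subject_id=subject_id, label=label, phq8=phq8, sex=sex)
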
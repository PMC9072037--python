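import numpy as np
import pytest

from tcmrank.corpus import MedicalCase, build_vocabulary
from tcmrank.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_cases():
    """Five hand-built cases with transparent co-occurrence structure."""
    return [
        MedicalCase("c1", ["cough", "fever"], ["red"], ["white"], ["rapid"], {"heat", "lung"}),
        MedicalCase("c2", ["cough", "phlegm"], ["pale"], ["white"], ["slow"], {"lung"}),
        MedicalCase("c3", ["fever", "thirst"], ["red"], ["yellow"], ["rapid"], {"heat"}),
        MedicalCase("c4", ["fatigue"], ["pale"], ["thin"], ["weak"], {"deficiency"}),
        MedicalCase("c5", ["cough", "fatigue"], ["pale"], ["white"], ["weak"], {"lung", "deficiency"}),
    ]


@pytest.fixture(scope="session")
def tiny_vocab(tiny_cases):
    return build_vocabulary(tiny_cases)


@pytest.fixture(scope="session")
def small_corpus():
    """A modest generated corpus shared by the statistics and model tests."""
    cfg = GeneratorConfig(
        n_cases=400,
        seed=11,
        field_vocab_sizes={"engraving_symptoms": 120, "tongue": 15, "moss": 15, "pulse": 18},
    )
    cases, truth = generate_corpus(cfg)
    return cases, truth


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    cases, _ = small_corpus
    return build_vocabulary(cases)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
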
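import numpy as np
import pytest

from ssoddi.data_synth import SynthSpec, generate_synthetic_dti
from ssoddi.text_preprocess import AnnotatedSentence


@pytest.fixture(scope="session")
def synth_default():
    """Default synthetic DTI dataset, seed 7 (shared across tests)."""
    spec = SynthSpec(seed=7)
    dataset, X, y, pair_index = generate_synthetic_dti(spec)
    return spec, dataset, X, y, pair_index


@pytest.fixture
def aspirin_sentence():
    tokens = "Aspirin might reduce the effect of probenecid".split()
    return AnnotatedSentence(
        tuple(tokens), ((0, 1, "Aspirin"), (6, 7, "probenecid"))
    )


def random_annotated_sentence(rng: np.random.Generator, n_mentions: int,
                              drug_names=None) -> AnnotatedSentence:
    """A synthetic sentence with n single-token drug mentions at random slots."""
    n_tokens = n_mentions + int(rng.integers(3, 10))
    filler = [f"w{int(rng.integers(100))}" for _ in range(n_tokens)]
    slots = sorted(rng.choice(n_tokens, size=n_mentions, replace=False))
    names = drug_names or [f"drug{k}" for k in range(n_mentions)]
    mentions = tuple((int(s), int(s) + 1, names[k]) for k, s in enumerate(slots))
    tokens = list(filler)
    for s, _e, name in mentions:
        tokens[s] = name
    return AnnotatedSentence(tuple(tokens), mentions)
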
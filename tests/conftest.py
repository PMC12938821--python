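"""Shared fixtures: a seeded synthetic library, an overfit toy VAE, and a
trained KAL model.  Session-scoped because training is the expensive step."""

import numpy as np
import pytest

from kinomanifold.kal import AssemblyPolicy, RfConfig, assemble_training_set, train_kal
from kinomanifold.latent_core import VaeConfig, train_vae
from kinomanifold.synthkit import LibrarySpec, generate_toy_library


@pytest.fixture(scope="session")
def toy_library():
    """Three fused-aromatic kinase-like families (50 each) + 180 background."""
    return generate_toy_library(LibrarySpec(seed=11))


@pytest.fixture(scope="session")
def vae_corpus(toy_library):
    """A 30-molecule cross-family slice used to overfit the toy VAE."""
    by_family = {}
    for m in toy_library:
        by_family.setdefault(m.family, []).append(m)
    corpus = []
    for fam in sorted(by_family):
        corpus.extend(by_family[fam][:8])
    return corpus[:30]


@pytest.fixture(scope="session")
def toy_vae(vae_corpus):
    cfg = VaeConfig(latent_dim=8, hidden_dim=128, epochs=600, seed=7)
    return train_vae(vae_corpus, cfg, max_length=40)


@pytest.fixture(scope="session")
def toy_assembly(toy_library):
    positives = [m for m in toy_library if m.family == "SRC"]
    kin_neg = [m for m in toy_library if m.family in ("LCK", "EGFR")]
    background = [m for m in toy_library if m.family == "background"]
    policy = AssemblyPolicy(background_subsample=len(background), seed=3)
    return assemble_training_set(positives, kin_neg, background, policy)


@pytest.fixture(scope="session")
def kal_model(toy_assembly):
    return train_kal(toy_assembly, RfConfig(n_estimators=200, seed=3))
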
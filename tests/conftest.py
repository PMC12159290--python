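import numpy as np
import pytest

from scadapt.classify import DualHeadClassifier, TrainSchedule
from scadapt.resvae import ResVAE
from scadapt.simulate import SyntheticSpec, generate_two_domain


@pytest.fixture(scope="session")
def small_two_domain():
    """A small two-domain dataset shared by classifier/attribution tests."""
    spec = SyntheticSpec(n_source=300, n_target=300, n_features=16,
                         d_true=4, seed=7)
    return generate_two_domain(spec)


@pytest.fixture(scope="session")
def small_vae(small_two_domain):
    vae = ResVAE(latent_dim=4, encoder_block_dims=(12,), epochs=30, seed=7)
    vae.fit(small_two_domain.source.values)
    return vae


@pytest.fixture(scope="session")
def small_classifier(small_two_domain, small_vae):
    clf = DualHeadClassifier(
        stem=small_vae,
        schedule=TrainSchedule(total_epochs=40, head_only_epochs=30,
                               batch_size=64, seed=8),
        transfer="adain")
    clf.fit(small_two_domain.source, small_two_domain.source_labels.response)
    return clf
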
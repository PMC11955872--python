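import warnings

import numpy as np
import pytest

from icnsim import channels as ch
from icnsim import membrane as mb
from icnsim import synthetic
from icnsim import transcriptome as tx


@pytest.fixture(scope="session")
def full_model():
    """All-14-channel model with the published conductances, leak balanced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mb.build_model(ch.GENES, label="full")
    return model.with_leak(mb.tune_leak(model))


@pytest.fixture(scope="session")
def tonic_model():
    """Na + Kv3.1 genotype: a tonically firing fixture."""
    model = mb.build_model(("Scn1a", "Kcnc1"), label="tonic-fixture")
    return model.with_leak(mb.tune_leak(model))


@pytest.fixture(scope="session")
def small_ct():
    """Seeded synthetic Ct matrix small enough for fast library runs."""
    return synthetic.generate_ct(synthetic.SyntheticCtParams(n_neurons=120), seed=11)


@pytest.fixture(scope="session")
def small_library(small_ct):
    return tx.collapse_genotypes(tx.binarize(small_ct, 15.0), 15.0, source="synthetic")
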
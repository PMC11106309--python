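import numpy as np
import pandas as pd
import pytest

from tcrlatent.airr import prepare
from tcrlatent.physchem import default_feature_table, encode_batch
from tcrlatent.simulate import SyntheticSpec, generate_repertoire, toy_germline


@pytest.fixture(scope="session")
def feature_table():
    return default_feature_table()


@pytest.fixture(scope="session")
def germline():
    return toy_germline()


@pytest.fixture(scope="session")
def germline_frame(germline):
    return germline.v_table().reset_index()


@pytest.fixture(scope="session")
def small_repertoire(germline):
    """500 synthetic AIRR records with stored ground-truth factors."""
    return generate_repertoire(germline,
                               SyntheticSpec(n_records=500, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_repertoire, germline_frame):
    """QC'd, annotated, split CDR2+3 feature strings for the 500 records."""
    return prepare(small_repertoire, germline_frame, seed=11)


@pytest.fixture(scope="session")
def tiny_trained_cvae(germline, germline_frame):
    """A quickly trained small-capacity model for interface-level tests.

    Deliberately tiny (few hundred sequences, few epochs): exercises the
    training loop, embedding and decoding contracts without aiming for
    converged reconstruction.
    """
    from tcrlatent.cvae import CVAEConfig, build_cvae, train

    rep = generate_repertoire(germline, SyntheticSpec(n_records=400, seed=3))
    ds = prepare(rep, germline_frame, seed=3)
    cfg = CVAEConfig(capacity=2.0, seed=3, batch_size=128, max_epochs=3,
                     patience=3)
    xt = encode_batch(ds.train["feature_text"], cfg.l_max)
    xv = encode_batch(ds.val["feature_text"], cfg.l_max)
    model, history = train(build_cvae(cfg), xt, xv, cfg)
    return model, ds, history
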
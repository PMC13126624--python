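import numpy as np
import pytest

from atcgen import Seq2SeqConfig, train_seq2seq
from atcgen.synthetic import GrammarSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_grammar():
    """A small noise-free single-code dataset, shared across tests."""
    spec = GrammarSpec(label_count_probs=(1.0, 0, 0, 0), max_len=14, seed=7)
    records, matrix = generate_dataset(spec, 140)
    return spec, records, matrix


@pytest.fixture(scope="session")
def tiny_model(tiny_grammar):
    """A quickly trained BiLSTM plus its held-out records."""
    _, records, _ = tiny_grammar
    cfg = Seq2SeqConfig(
        architecture="bilstm", seed=0, max_epochs=50, patience=12, batch_size=32
    )
    model = train_seq2seq(records[:110], records[110:130], cfg)
    return model, records[130:]


@pytest.fixture(scope="session")
def multilabel_records():
    """A dataset with a realistic mixture of single- and multi-code compounds."""
    spec = GrammarSpec(seed=11)
    records, matrix = generate_dataset(spec, 200)
    return records, matrix
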
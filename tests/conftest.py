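import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def generic_tsv(tmp_path):
    p = tmp_path / "generic.tsv"
    p.write_text(
        "id\tcount\tfunctional\n"
        "clone_a\t5\ttrue\n"
        "clone_b\t2\tfalse\n"
        "clone_c\t1\ttrue\n"
    )
    return p


@pytest.fixture
def immunoseq_tsv(tmp_path):
    p = tmp_path / "immunoseq.tsv"
    p.write_text(
        "rearrangement\ttemplates\tframe_type\n"
        "CASSL\t5\tIn\n"
        "CASSQ\t2\tOut\n"
        "CASSR\t1\tStop\n"
    )
    return p


@pytest.fixture
def airr_tsv(tmp_path):
    p = tmp_path / "airr.tsv"
    p.write_text(
        "junction_aa\tduplicate_count\tproductive\n"
        "CASSL\t5\tT\n"
        "CASSQ\t2\tF\n"
        "CASSR\t1\tT\n"
    )
    return p
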
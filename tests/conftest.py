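import numpy as np
import pytest

from phostress import formats


@pytest.fixture(scope="session")
def de_table():
    return formats.load_de_gene_table()


@pytest.fixture(scope="session")
def pho_table():
    return formats.load_pho_box_table()


@pytest.fixture()
def toy_annotation():
    """A 600 nt contig with one gene per strand and known promoters."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    feats = [
        formats.CdsFeature("fwd", 301, 420, "+"),
        formats.CdsFeature("rev", 1, 120, "-"),
    ]
    return formats.GenomeAnnotation("toy", seq, feats)
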
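import numpy as np
import pandas as pd
import pytest

from heritkit.pedigree import Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pedigree(rows):
    """rows: (fid, iid, father, mother, sex, zygosity) tuples."""
    return Pedigree(
        pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "zygosity"])
    )


@pytest.fixture
def nuclear_family():
    """Two parents, two kids, one grandchild via kid1 and an in-law."""
    return make_pedigree(
        [
            ("f1", "gpa", "0", "0", "1", "."),
            ("f1", "gma", "0", "0", "2", "."),
            ("f1", "dad", "gpa", "gma", "1", "."),
            ("f1", "aunt", "gpa", "gma", "2", "."),
            ("f1", "mom", "0", "0", "2", "."),
            ("f1", "kid", "dad", "mom", "1", "."),
        ]
    )
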
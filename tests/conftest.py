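import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import combosc as csc

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_matrix(counts, cell_ids=None, gene_ids=None, normalize=False):
    """Small dense-count ExpressionMatrix builder for tests."""
    counts = np.asarray(counts)
    n, g = counts.shape
    m = csc.ExpressionMatrix(
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"G{j}" for j in range(g)],
        counts=counts,
    )
    return csc.normalize_log2_tpm(m) if normalize else m


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic fixture shared across the suite (seed 1)."""
    return csc.default_fixture(seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """Five-line, three-drug panel with distinguishable profiles."""
    rng = np.random.default_rng(7)
    genes = [f"G{j}" for j in range(40)]
    prof = pd.DataFrame(rng.gamma(2.0, 2.0, size=(5, 40)),
                        index=[f"L{i}" for i in range(5)], columns=genes)
    sens = pd.DataFrame(rng.uniform(0, 1, size=(5, 3)),
                        index=prof.index, columns=["dA", "dB", "dC"])
    return csc.ReferencePanel(profiles=prof, sensitivity=sens)
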
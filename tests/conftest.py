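import numpy as np
import pandas as pd
import pytest

import tempodeg as td


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic experiment with planted temporal patterns,
    treatment effects and modules (the documented reference conditions)."""
    exp, truth = td.simulate_counts(td.SimulationSpec())
    return exp, truth


@pytest.fixture(scope="session")
def default_de(default_sim):
    """Preprocessing plus the four Wald contrasts on the default experiment."""
    exp, truth = default_sim
    exp = td.filter_genes(exp)
    s = td.size_factors(exp)
    norm = td.normalize_transform(exp, s)
    de = {
        cid: td.wald_test(exp, s, pair)
        for cid, pair in {
            "A": ("sham", "injured_1d"),
            "B": ("sham", "injured_1wk"),
            "C": ("injured_1d", "injured_1wk"),
            "T": ("sham", "treated_1d"),
        }.items()
    }
    return exp, truth, s, norm, de


def make_de_table(genes, lfc, pvalue, fdr=None):
    """Construct a minimal DE table for classifier tests."""
    lfc = np.asarray(lfc, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    fdr = pvalue if fdr is None else np.asarray(fdr, dtype=float)
    return pd.DataFrame(
        {
            "base_mean": np.ones(len(genes)),
            "log2FC": lfc,
            "se": np.ones(len(genes)),
            "stat": lfc,
            "pvalue": pvalue,
            "fdr": fdr,
            "dispersion": np.full(len(genes), 0.1),
        },
        index=pd.Index(genes, name="gene"),
    )
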
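import numpy as np
import pandas as pd
import pytest

from m3cax.constants import GROUPS
from m3cax.datatypes import IntensityMatrix, MetaboliteMeta, SampleMeta
from m3cax.mfa import default_network


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def true_fluxes(network):
    from m3cax.mfa.network import DEFAULT_TRUE_FREE_FLUXES
    return network.complete_fluxes(DEFAULT_TRUE_FREE_FLUXES)


def make_matrix(values, tissue="liver", groups=GROUPS, n_rep=None,
                formula="C6H12O6"):
    """Build an IntensityMatrix from a 2-D array; columns grouped by group."""
    values = np.asarray(values, dtype=float)
    n_met, n_samp = values.shape
    if n_rep is None:
        n_rep = n_samp // len(groups)
    samples = [SampleMeta(f"{tissue}_{g}_{r}", tissue, g, r)
               for g in groups for r in range(1, n_rep + 1)]
    assert len(samples) == n_samp
    mets = [MetaboliteMeta(f"M{i+1:03d}", f"m{i+1}", formula, "other")
            for i in range(n_met)]
    df = pd.DataFrame(values, index=[m.metabolite_id for m in mets],
                      columns=[s.sample_id for s in samples])
    return IntensityMatrix(df, samples, mets, scale="raw")


@pytest.fixture
def matrix_factory():
    return make_matrix
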
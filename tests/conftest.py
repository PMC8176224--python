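import numpy as np
import pandas as pd
import pytest

import cernapipe as cp


def make_matrix(values, transcript_ids=None, groups=("A", "B"), reps=3,
                rna_class="mRNA", species="cattle"):
    """Small expression matrix from a 2-d array; columns group:rep."""
    values = np.asarray(values, dtype=float)
    cols = [f"{g}:{r}" for g in groups for r in range(1, reps + 1)]
    assert values.shape[1] == len(cols)
    ids = transcript_ids or [f"t{i}" for i in range(values.shape[0])]
    return cp.ExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols),
                               species=species, rna_class=rna_class)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions (read-only)."""
    return cp.run_all(cp.SimulationConfig(seed=3), with_associations=False)


@pytest.fixture(scope="session")
def default_sim():
    """Bundle + truth at default conditions (read-only)."""
    return cp.simulate(cp.SimulationConfig(seed=5))
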
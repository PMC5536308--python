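import io

import numpy as np
import pandas as pd
import pytest

from gexpipe import proteomics, simulate


@pytest.fixture
def small_cfg():
    return simulate.SimConfig(
        n_genes=300,
        n_proteins=120,
        conditions=("wt", "mutA", "mutB", "mutC"),
        overlap_spec={
            ("mutA",): 15,
            ("mutB",): 15,
            ("mutC",): 15,
            ("mutA", "mutB"): 5,
            ("mutA", "mutB", "mutC"): 5,
        },
        de_fraction=0.2,
        nb_dispersion=0.05,
        go_terms=20,
        seed=42,
    )


@pytest.fixture
def small_truth(small_cfg):
    return simulate.gen_truth(small_cfg)


def ratio_table_from_frame(df: pd.DataFrame) -> proteomics.RatioTable:
    """Round-trip a generated protein-groups frame through the parser."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return proteomics.read_protein_groups(buf)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
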
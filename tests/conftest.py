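import numpy as np
import pandas as pd
import pytest

from top3seq.diffexpr import CountMatrix, run_de
from top3seq.simulate import SimConfig, gen_annotation, gen_expression


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_annotation(default_cfg):
    return gen_annotation(default_cfg)


@pytest.fixture(scope="session")
def default_expression(default_cfg, default_annotation):
    _, truth_feats = default_annotation
    return gen_expression(default_cfg, truth_feats)


@pytest.fixture(scope="session")
def default_de(default_expression):
    """Null-mutant vs wild-type transcript-level DE on the default sim."""
    tx, _, sheet, truth = default_expression
    m = CountMatrix(tx, sheet.set_index("sample_id")["condition"])
    res = run_de(m, ("wt", "null26"))
    return res, truth


@pytest.fixture(scope="session")
def small_annotation():
    cfg = SimConfig(seed=11, n_genes=80)
    return gen_annotation(cfg)


def make_count_matrix(counts: np.ndarray, conditions: list[str]) -> CountMatrix:
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    df = pd.DataFrame(
        counts, columns=samples,
        index=[f"f{i}" for i in range(counts.shape[0])],
    )
    return CountMatrix(df, pd.Series(conditions, index=samples))
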
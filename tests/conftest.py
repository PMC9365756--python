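import numpy as np
import pandas as pd
import pytest

from neurostack.datamodel import Dataset


@pytest.fixture
def tiny_csv(tmp_path):
    p = tmp_path / "tiny.csv"
    p.write_text("age,bm_47,diagnosis\n63,0,HC\n71,12,AD\n68,3,AD\n")
    return p


@pytest.fixture
def mixed_dataset():
    """Three-class table with numeric, nominal and region-count columns."""
    rng = np.random.default_rng(7)
    n = 30
    y = pd.Series(["AD"] * 12 + ["bvFTD"] * 8 + ["HC"] * 10)
    X = pd.DataFrame(
        {
            "age": rng.normal(70, 6, n),
            "gender": rng.choice(["M", "F"], n),
            "cog_0": rng.normal(0, 1, n),
            "bm_1": rng.poisson(2, n).astype(float),
            "bm_2": rng.poisson(1, n).astype(float),
        }
    )
    kinds = {"age": "numeric", "gender": "nominal", "cog_0": "numeric",
             "bm_1": "region_count", "bm_2": "region_count"}
    return Dataset(X, kinds, y, ["AD", "bvFTD", "HC"])


@pytest.fixture
def separable_dataset():
    """Two well-separated Gaussian classes on two features + one noise column."""
    rng = np.random.default_rng(3)
    n = 40
    y = pd.Series(["A"] * n + ["B"] * n)
    X = pd.DataFrame(
        {
            "f0": np.concatenate([rng.normal(3, 0.5, n), rng.normal(-3, 0.5, n)]),
            "f1": np.concatenate([rng.normal(-3, 0.5, n), rng.normal(3, 0.5, n)]),
            "noise": rng.normal(0, 1, 2 * n),
        }
    )
    kinds = {c: "numeric" for c in X.columns}
    return Dataset(X, kinds, y, ["A", "B"])
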
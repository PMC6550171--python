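import numpy as np
import pandas as pd
import pytest

from manuka import GeneratorConfig, generate_honey_dataset


def small_sizes():
    return {
        "2014/15": {"M": 30, "MB": 15, "K": 10, "NM": 35, "AU": 10, "NN": 15},
        "2015/16": {"M": 30, "MB": 15, "K": 10, "NM": 35, "AU": 10, "NN": 15},
        "archive": {"M": 10, "MB": 5, "K": 5, "NM": 10, "AU": 5, "NN": 5},
    }


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(sample_sizes=small_sizes(), seed=7)


@pytest.fixture(scope="session")
def honey(small_config):
    return generate_honey_dataset(small_config)


def planted_tree_data(n_per_class=100, seed=0, boundary=400.0, gap=0.05):
    """Six-class table with a dominant 3-PA separation planted at a boundary.

    Three classes sit strictly above the boundary and three strictly below,
    with a clear gap around it, while the classes within each side overlap
    heavily and the DNA markers are pure noise — so the best first split is
    the 3-PA boundary. The gap half-width is ``gap`` (fraction of the
    boundary), keeping the midpoint threshold within that band.
    """
    rng = np.random.default_rng(seed)
    hi = boundary * (1 + gap)
    lo = boundary * (1 - gap)
    rows = []
    for cls in ("M", "K", "AU"):  # above the boundary
        pa = hi * np.exp(rng.exponential(0.5, n_per_class))
        rows += [
            {"supplier_label": cls, "3-PA": p,
             "manuka_dna": rng.normal(33, 4), "kanuka_dna": rng.normal(33, 4)}
            for p in pa
        ]
    for cls in ("MB", "NM", "NN"):  # below the boundary
        pa = lo * rng.random(n_per_class) ** 0.5
        rows += [
            {"supplier_label": cls, "3-PA": p,
             "manuka_dna": rng.normal(33, 4), "kanuka_dna": rng.normal(33, 4)}
            for p in pa
        ]
    return pd.DataFrame(rows)
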
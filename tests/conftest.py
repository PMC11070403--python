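import numpy as np
import pandas as pd
import pytest

from funcsignal import BipartiteNetwork, TraitColumn, TraitTable


@pytest.fixture
def mixed_table() -> TraitTable:
    """Six species, one trait of each plain kind plus a multilabel group."""
    df = pd.DataFrame(
        {
            "mass": [1.0, 2.5, 4.0, 8.0, 16.0, 3.0],
            "size_rank": ["small", "medium", "large", "large", "medium",
                          "small"],
            "diet": ["omni", "gran", "omni", "insect", "gran", "insect"],
            "hibernates": [0, 1, 0, 0, 1, 1],
            "life_ground": [1, 1, 0, 0, 1, 1],
            "life_arboreal": [0, 1, 1, 0, 0, 1],
        },
        index=[f"sp{i}" for i in range(6)],
    )
    schema = (
        TraitColumn("mass", "continuous"),
        TraitColumn("size_rank", "ordinal",
                    levels=("small", "medium", "large")),
        TraitColumn("diet", "nominal"),
        TraitColumn("hibernates", "binary"),
        TraitColumn("life_ground", "multilabel", group="lifestyle"),
        TraitColumn("life_arboreal", "multilabel", group="lifestyle"),
    )
    return TraitTable(df, schema)


@pytest.fixture
def toy_network() -> BipartiteNetwork:
    inc = pd.DataFrame(
        [[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 1]],
        index=["f0", "f1", "f2", "f3"],
        columns=["h0", "h1", "h2", "h3"],
    )
    return BipartiteNetwork(inc)


def random_continuous_table(rng: np.random.Generator, n_species: int,
                            n_traits: int) -> TraitTable:
    X = rng.normal(size=(n_species, n_traits))
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(n_species)],
                      columns=[f"x{j}" for j in range(n_traits)])
    schema = tuple(TraitColumn(f"x{j}", "continuous")
                   for j in range(n_traits))
    return TraitTable(df, schema)
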
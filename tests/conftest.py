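import numpy as np
import pandas as pd
import pytest

from mitoegt import Cladogram, GeneStateMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240125)


@pytest.fixture
def balanced4():
    return Cladogram.from_newick("((A,B),(C,D));")


@pytest.fixture
def five_leaf():
    return Cladogram.from_newick("(((A,B),C),(D,E));")


@pytest.fixture
def small_matrix():
    df = pd.DataFrame(
        {
            "g1": ["M", "M", "N", "N"],
            "g2": ["M", "L", "M", "?"],
            "g3": ["D", "N", "L", "M"],
        },
        index=["A", "B", "C", "D"],
    )
    return GeneStateMatrix(
        df, evidence={"A": "genome", "B": "transcriptome",
                      "C": "genome", "D": "transcriptome"}
    )


def random_state_matrix(rng, n_taxa=6, n_genes=8, states="MNLD?", p=None):
    taxa = [f"T{i}" for i in range(n_taxa)]
    genes = [f"g{j}" for j in range(n_genes)]
    cells = rng.choice(list(states), size=(n_taxa, n_genes), p=p)
    ev = {
        t: ("transcriptome" if rng.random() < 0.5 else "genome") for t in taxa
    }
    return GeneStateMatrix(
        pd.DataFrame(cells, index=taxa, columns=genes), evidence=ev
    )
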
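import numpy as np
import pandas as pd
import pytest

from regulonrank.io_formats import ExpressionMatrix, RegulatoryNetwork


def make_expression(
    n_genes: int = 6, n_reps: int = 3, genotype: str = "WT", seed: int = 0
) -> ExpressionMatrix:
    """A small well-formed matrix with one genotype and two treatments."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(1, n_genes + 1)]
    samples, rows = [], []
    for treatment in ("saline", "caerulein"):
        for r in range(1, n_reps + 1):
            samples.append(f"{genotype}_{treatment}_{r}")
            rows.append({"sample_id": samples[-1], "genotype": genotype,
                         "treatment": treatment, "replicate": r})
    values = pd.DataFrame(
        rng.normal(8, 1, size=(n_genes, len(samples))),
        index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    design = pd.DataFrame(rows).set_index("sample_id")
    return ExpressionMatrix(values, design)


@pytest.fixture
def small_em() -> ExpressionMatrix:
    return make_expression()


@pytest.fixture
def small_network() -> RegulatoryNetwork:
    pairs = {("T1", "g1"), ("T1", "g2"), ("T2", "g3")}
    return RegulatoryNetwork(pairs, universe={"g1", "g2", "g3", "g4"})
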
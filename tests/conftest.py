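import numpy as np
import pandas as pd
import pytest

from traplate import (
    ExpressionMatrix,
    GeneratorConfig,
    SampleSheet,
    generate_translatome_dataset,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with simple values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 4.0], [2.5, 0.0], [10.0, 7.5]],
            index=pd.Index(["geneA", "geneB", "geneC"], name="gene_id"),
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def twelve_sample_sheet() -> SampleSheet:
    """2 fractions x 2 groups x 3 replicates, the study design."""
    rows = [
        (f"{f}_{g}_{r}", f, g, r)
        for f in ("IN", "IP")
        for g in ("control", "condition")
        for r in (1, 2, 3)
    ]
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "fraction", "group", "replicate"]))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-size synthetic dataset (2,000 genes) for fast tests."""
    cfg = GeneratorConfig(n_genes=2000, n_de_up=30, n_de_down=30, seed=7)
    matrix, sheet, truth = generate_translatome_dataset(cfg)
    return cfg, matrix, sheet, truth


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study conditions (15,000 genes), fixed seed."""
    cfg = GeneratorConfig(seed=1)
    matrix, sheet, truth = generate_translatome_dataset(cfg)
    return cfg, matrix, sheet, truth


def random_expression_frame(rng: np.random.Generator, n_genes: int, n_samples: int) -> pd.DataFrame:
    values = rng.gamma(2.0, 10.0, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
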
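import numpy as np
import pytest

from tensorfe.io_design import (
    Condition,
    ExpressionMatrix,
    SampleDesign,
    sleep_deprivation_design,
)
from tensorfe.tensorize import ExpressionTensor, build_tensor, standardize


@pytest.fixture
def sleep_design() -> SampleDesign:
    return sleep_deprivation_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_design() -> SampleDesign:
    """Fully observed 3 x 2 x 2 design (12 samples)."""
    assignments = {}
    for cond in Condition:
        for k in (1, 2):
            for m in (1, 2):
                assignments[f"{cond.name}_k{k}_m{m}"] = (cond, k, m)
    return SampleDesign(assignments=assignments, n_replicates=2, n_hours=2)


def random_matrix(design: SampleDesign, n_genes: int, rng) -> ExpressionMatrix:
    sample_ids = design.sample_ids
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=sample_ids,
        values=rng.normal(5.0, 2.0, size=(n_genes, len(sample_ids))),
    )


def random_standardized_tensor(design, n_genes, rng) -> ExpressionTensor:
    return standardize(build_tensor(random_matrix(design, n_genes, rng), design))
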
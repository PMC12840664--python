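"""Tensor construction and per-slice standardization.

A study's expression matrix is reshaped into a 4-mode tensor
``x[i, j, k, m]`` — gene i, condition j (HC/SD/RS), replicate k, hour m.
Cells of the (j, k, m) grid with no assigned sample are *missing* and
zero-filled; a boolean mask records which cells were observed.

Before decomposition each observed gene-slice is standardized so that,
summing over genes i at fixed (j, k, m),

    sum_i x_ijkm   = 0
    sum_i x_ijkm^2 = N

i.e. zero mean and unit root-mean-square across genes.  Missing slices are
left identically zero: the zero-fill is part of the model and an all-zero
slice cannot satisfy the unit-RMS constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_design import ExpressionMatrix, SampleDesign

__all__ = ["ExpressionTensor", "build_tensor", "build_tensor_3mode", "standardize"]


@dataclass
class ExpressionTensor:
    """4-mode expression tensor with an observed-cell mask.

    ``values`` has shape (N, J, K, M); ``observed`` has shape (J, K, M)
    and flags the cells backed by a real sample.  Entries at unobserved
    cells are exactly zero.  3-mode studies are represented with M = 1.
    """

    values: np.ndarray
    observed: np.ndarray
    gene_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-mode (N, J, K, M)")
        if self.observed.shape != self.values.shape[1:]:
            raise ValueError("observed mask must have shape (J, K, M)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length must match mode-1 size")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 genes")
        if np.any(self.values[:, ~self.observed] != 0.0):
            raise ValueError("unobserved cells must be exactly zero")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


def build_tensor(matrix: ExpressionMatrix, design: SampleDesign) -> ExpressionTensor:
    """Arrange a genes x samples matrix into the (N, J, K, M) tensor.

    Each sample column is placed at the (condition, replicate, hour) cell
    the design assigns it; cells with no sample are zero and flagged
    unobserved.  Gene order is preserved from the matrix.
    """
    J, K, M = design.shape
    col = {sid: idx for idx, sid in enumerate(matrix.sample_ids)}
    values = np.zeros((matrix.n_genes, J, K, M))
    observed = np.zeros((J, K, M), dtype=bool)
    for sid, (cond, k, m) in design.assignments.items():
        if sid not in col:
            raise ValueError(f"design sample {sid!r} not found in expression matrix")
        values[:, int(cond) - 1, k - 1, m - 1] = matrix.values[:, col[sid]]
        observed[int(cond) - 1, k - 1, m - 1] = True
    return ExpressionTensor(
        values=values, observed=observed, gene_ids=list(matrix.gene_ids)
    )


def build_tensor_3mode(
    matrix: ExpressionMatrix, design: SampleDesign
) -> ExpressionTensor:
    """Build a gene x condition x replicate tensor (no hour axis).

    The design must declare a single hour level; internally the result is
    the same 4-mode container with M = 1, so every downstream stage uses
    one code path.
    """
    if design.n_hours != 1:
        raise ValueError(
            f"3-mode design must have n_hours = 1, got {design.n_hours}"
        )
    return build_tensor(matrix, design)


def standardize(tensor: ExpressionTensor) -> ExpressionTensor:
    """Center and scale every observed slice to mean 0, sum of squares N.

    Returns a new tensor; unobserved slices stay exactly zero.

    Raises
    ------
    ValueError
        If the tensor is already standardized, or an observed slice is
        constant across genes (unit RMS is then unattainable).
    """
    if tensor.standardized:
        raise ValueError("tensor is already standardized")
    values = tensor.values.copy()
    for j, k, m in np.argwhere(tensor.observed):
        x = values[:, j, k, m]
        centered = x - x.mean()
        rms = np.sqrt(np.mean(centered**2))
        if rms == 0.0:
            raise ValueError(
                f"observed slice (j={j + 1}, k={k + 1}, m={m + 1}) is constant "
                "across genes; cannot scale to unit RMS"
            )
        values[:, j, k, m] = centered / rms
    return ExpressionTensor(
        values=values,
        observed=tensor.observed.copy(),
        gene_ids=list(tensor.gene_ids),
        standardized=True,
    )
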
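"""Higher-order SVD of the expression tensor, and a PCA baseline.

HOSVD (the Tucker decomposition with per-mode orthonormal factors) writes
the standardized tensor as

    x_ijkm = sum_{l1 l2 l3 l4} G(l1,l2,l3,l4) u_{l1 i} u_{l2 j} u_{l3 k} u_{l4 m}

where each factor matrix holds the left singular vectors of the
corresponding mode-n unfolding and G is the (all-orthogonal) core tensor
obtained by contracting x with the transposed factors.  The core entry
G(l1,l2,l3,l4) weighs how much the combination of per-mode components
(l1,l2,l3,l4) contributes to the data.

Unfolding convention: mode n on rows, remaining modes in ascending order
on columns.  Sign convention: every factor column is flipped so that its
largest-magnitude entry is positive (ties to the first such entry), and
the core is computed after flipping; this removes the sign indeterminacy
of the SVD so that repeated runs are bit-reproducible.

The PCA baseline applies an ordinary SVD to the matrix of observed sample
columns only — the comparison method for asking whether plain PCA finds
the same condition-dependent structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensorize import ExpressionTensor

__all__ = ["HosvdResult", "PcaBaseline", "hosvd", "reconstruct", "pca_baseline"]


@dataclass
class HosvdResult:
    """Per-mode factor matrices and core tensor.

    ``factors[0]`` is the gene-mode matrix (N x R1, economy size
    R1 = min(N, J*K*M)); ``factors[1..3]`` are the square condition /
    replicate / hour factors.  ``core`` has shape (R1, J, K, M) and the
    same Frobenius norm as the input tensor.
    """

    factors: list[np.ndarray]
    core: np.ndarray
    gene_ids: list[str]

    @property
    def gene_factor(self) -> np.ndarray:
        return self.factors[0]

    @property
    def condition_factor(self) -> np.ndarray:
        return self.factors[1]

    @property
    def replicate_factor(self) -> np.ndarray:
        return self.factors[2]

    @property
    def hour_factor(self) -> np.ndarray:
        return self.factors[3]

    def gene_scores(self, component: int) -> np.ndarray:
        """Gene-mode singular value vector u_{l1 i} (1-based component)."""
        return self.factors[0][:, component - 1]


@dataclass
class PcaBaseline:
    """SVD of the genes x observed-samples unfolding."""

    loadings: np.ndarray  # observed samples x rank, orthonormal columns
    scores: np.ndarray  # genes x rank
    explained_variance_ratio: np.ndarray
    sample_cells: list[tuple[int, int, int]]  # 1-based (j, k, m) per column


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: mode on rows, remaining modes ascending on columns."""
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    return u * flip


def _multi_mode_product(x: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """Contract x with one matrix per mode: result = x x_0 M0 x_1 M1 ..."""
    out = x
    for mode, m in enumerate(mats):
        out = np.moveaxis(np.tensordot(m, out, axes=(1, mode)), 0, mode)
    return out


def hosvd(tensor: ExpressionTensor) -> HosvdResult:
    """Higher-order SVD of a standardized expression tensor.

    Each factor matrix holds the left singular vectors of the mode-n
    unfolding (economy size on the gene mode); the core is the tensor
    contracted with all transposed factors, so the decomposition is exact.

    Raises
    ------
    ValueError
        If the tensor is not standardized or any mode is degenerate.
    """
    if not tensor.standardized:
        raise ValueError("hosvd expects a standardized tensor")
    x = tensor.values
    if min(x.shape) < 1 or x.shape[0] < 2:
        raise ValueError(f"degenerate tensor shape {x.shape}")
    factors = []
    for mode in range(4):
        u, _, _ = np.linalg.svd(_unfold(x, mode), full_matrices=False)
        factors.append(_fix_signs(u))
    core = _multi_mode_product(x, [f.T for f in factors])
    return HosvdResult(factors=factors, core=core, gene_ids=list(tensor.gene_ids))


def reconstruct(result: HosvdResult, core: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the HOSVD expansion; exact when the full core is used.

    A modified core (e.g. truncated to one entry) may be passed to obtain
    low-rank approximations.
    """
    core = result.core if core is None else core
    if core.ndim != 4 or any(
        c > f.shape[1] for c, f in zip(core.shape, result.factors)
    ):
        raise ValueError(
            f"core shape {core.shape} incompatible with factor ranks "
            f"{[f.shape[1] for f in result.factors]}"
        )
    mats = [f[:, :r] for f, r in zip(result.factors, core.shape)]
    return _multi_mode_product(core, mats)


def pca_baseline(tensor: ExpressionTensor) -> PcaBaseline:
    """PCA of the unfolded genes x observed-samples matrix.

    Columns are the observed (condition, replicate, hour) cells in
    ascending lexicographic (j, k, m) order; missing cells are dropped
    rather than zero-filled, so the matrix has exactly as many columns as
    the study has samples.
    """
    if not tensor.standardized:
        raise ValueError("pca_baseline expects a standardized tensor")
    cells = np.argwhere(tensor.observed)
    if len(cells) < 2:
        raise ValueError("need at least 2 observed cells for PCA")
    mat = tensor.values[:, cells[:, 0], cells[:, 1], cells[:, 2]]
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    # one flip vector applied to both sides keeps scores @ loadings.T == mat
    v = vt.T
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    u = u * flip
    total = float(np.sum(s**2))
    return PcaBaseline(
        loadings=v,
        scores=u * s,
        explained_variance_ratio=s**2 / total,
        sample_cells=[(j + 1, k + 1, m + 1) for j, k, m in cells],
    )
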
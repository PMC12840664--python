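"""Null-calibrated gene selection from a gene-mode singular value vector.

Under the null hypothesis a gene's factor score u_{l1 i} is Gaussian with
mean zero and some standard deviation sigma; the two-sided tail p-value is

    P_i = P_chi2_1[ > (u_i / sigma)^2 ]  =  2 (1 - Phi(|u_i| / sigma))

i.e. the survival function of a 1-d.f. chi-squared evaluated at the
squared z-score.  Genes with Benjamini-Hochberg-adjusted P below alpha
(default 0.01) are selected.

sigma must be estimated *excluding* the outliers about to be selected,
otherwise it is inflated and the selection loses power.  The calibration
used here scans a grid of candidate sigmas; for each candidate it computes
P, BH-adjusts, drops the genes passing the threshold, and histograms
1 - P_i of the retained genes into S equal-width bins on [0, 1].  If the
candidate sigma equals the true null scale, the retained 1 - P values are
uniform and the histogram is flat; the chosen sigma* minimizes the
population standard deviation of the bin counts (histogram flatness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SigmaOptimization",
    "SelectionResult",
    "compute_pvalues",
    "bh_adjust",
    "flatness",
    "optimize_sigma",
    "select_genes",
    "default_sigma_grid",
]

DEFAULT_BINS = 100
DEFAULT_ALPHA = 0.01
DEFAULT_GRID_SIZE = 100


@dataclass
class SigmaOptimization:
    """Record of the histogram-flatness scan over candidate sigmas."""

    grid: np.ndarray
    flatness_values: np.ndarray  # sigma_h per candidate; inf if none retained
    sigma_star: float
    n_bins: int
    histogram: np.ndarray  # bin counts of 1 - P at sigma_star


@dataclass
class SelectionResult:
    """Genes selected on one gene-mode component, with full provenance."""

    component: int
    u: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    selected: np.ndarray
    alpha: float
    optimization: SigmaOptimization
    gene_ids: list[str] | None = field(default=None)

    @property
    def sigma_star(self) -> float:
        return self.optimization.sigma_star

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    @property
    def selected_genes(self) -> set[str]:
        if self.gene_ids is None:
            raise ValueError("no gene IDs attached to this result")
        return {self.gene_ids[i] for i in self.selected_indices}


def compute_pvalues(u: np.ndarray, sigma: float) -> np.ndarray:
    """Two-sided Gaussian-null p-values P_i = chi2_1.sf((u_i / sigma)^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = np.asarray(u, dtype=float)
    return stats.chi2.sf((u / sigma) ** 2, df=1)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flatness(h: np.ndarray) -> float:
    """Population standard deviation of histogram bin counts.

    Zero for a perfectly flat histogram; the divisor is the bin count S,
    not S - 1.
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("empty histogram")
    if np.any(h < 0):
        raise ValueError("bin counts must be non-negative")
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def default_sigma_grid(u: np.ndarray, size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Log-spaced candidate sigmas spanning [0.1 s, 10 s], s = std(u).

    The decade on either side of the raw standard deviation covers both
    the overestimation regime (outliers inflating s) and underestimation.
    """
    s = float(np.std(np.asarray(u, dtype=float)))
    if s == 0:
        raise ValueError("u has zero variance; no sigma grid can be formed")
    return np.geomspace(0.1 * s, 10.0 * s, size)


def optimize_sigma(
    u: np.ndarray,
    grid: np.ndarray | None = None,
    n_bins: int = DEFAULT_BINS,
    alpha: float = DEFAULT_ALPHA,
) -> SigmaOptimization:
    """Choose the null sigma minimizing histogram flatness.

    For each candidate sigma the genes that would be selected (BH-adjusted
    P < alpha) are excluded, and the remaining 1 - P values are binned
    into ``n_bins`` equal-width bins on [0, 1]; the candidate with the
    flattest histogram wins, ties to the smallest sigma.  A candidate
    retaining no genes gets infinite flatness and is never chosen.
    """
    u = np.asarray(u, dtype=float)
    grid = default_sigma_grid(u) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("sigma grid must be non-empty and positive")
    if n_bins < 10:
        raise ValueError("need at least 10 histogram bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    flat = np.full(grid.size, np.inf)
    for idx, sigma in enumerate(grid):
        p = compute_pvalues(u, sigma)
        retained = bh_adjust(p) >= alpha
        if not retained.any():
            continue
        h, _ = np.histogram(1.0 - p[retained], bins=edges)
        flat[idx] = flatness(h)
    if not np.isfinite(flat).any():
        raise ValueError("every candidate sigma selects all genes; grid unusable")
    best = int(np.argmin(flat))  # argmin takes the first (smallest sigma) tie
    sigma_star = float(grid[best])
    p = compute_pvalues(u, sigma_star)
    retained = bh_adjust(p) >= alpha
    hist, _ = np.histogram(1.0 - p[retained], bins=edges)
    return SigmaOptimization(
        grid=grid,
        flatness_values=flat,
        sigma_star=sigma_star,
        n_bins=n_bins,
        histogram=hist,
    )


def select_genes(
    u: np.ndarray,
    component: int = 1,
    grid: np.ndarray | None = None,
    n_bins: int = DEFAULT_BINS,
    alpha: float = DEFAULT_ALPHA,
    gene_ids: list[str] | None = None,
) -> SelectionResult:
    """Calibrate sigma, assign p-values and select genes at adjusted P < alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    u = np.asarray(u, dtype=float)
    opt = optimize_sigma(u, grid=grid, n_bins=n_bins, alpha=alpha)
    p = compute_pvalues(u, opt.sigma_star)
    p_adj = bh_adjust(p)
    selected = p_adj < alpha
    return SelectionResult(
        component=component,
        u=u,
        p=p,
        p_adj=p_adj,
        selected=selected,
        alpha=alpha,
        optimization=opt,
        gene_ids=gene_ids,
    )
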
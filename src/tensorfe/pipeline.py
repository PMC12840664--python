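"""End-to-end orchestration: matrix -> tensor -> HOSVD -> gene selection.

``run_pipeline`` executes the whole unsupervised feature-extraction
workflow for one study: tensorize the expression matrix over its design,
standardize each observed slice, decompose, pick the constant replicate
and hour components, classify the condition components, and — for every
condition component with a non-trivial sleep-response pattern — choose the
gene component with the largest core weight and run sigma-calibrated gene
selection on it.  The run report records every chosen index, sigma*, gene
counts and parameter values, so a run is fully reproducible from the
report plus the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gene_select, pattern_select
from .decomposition import HosvdResult, hosvd
from .io_design import (
    ExpressionMatrix,
    SampleDesign,
    SelectionTable,
    write_run_report,
    write_selection,
)
from .pattern_select import ComponentChoice, PatternLabel
from .tensorize import ExpressionTensor, build_tensor, standardize

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "overlap_counts"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs of one pipeline run (all have study defaults)."""

    alpha: float = gene_select.DEFAULT_ALPHA
    delta: float = pattern_select.DEFAULT_DELTA
    theta: float = pattern_select.DEFAULT_THETA
    n_bins: int = gene_select.DEFAULT_BINS
    sigma_grid_size: int = gene_select.DEFAULT_GRID_SIZE
    search_limit: int = pattern_select.DEFAULT_SEARCH_LIMIT
    output_dir: Path | None = None


@dataclass
class ComponentSelection:
    """Gene selection attached to one interesting condition component."""

    choice: ComponentChoice
    result: gene_select.SelectionResult

    @property
    def selected_genes(self) -> set[str]:
        return self.result.selected_genes


@dataclass
class PipelineResult:
    tensor: ExpressionTensor
    hosvd: HosvdResult
    l3: int
    l4: int
    selections: list[ComponentSelection]
    report: dict = field(default_factory=dict)


def _stage(name: str):
    """Re-raise stage errors with the failing stage named."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def run_pipeline(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on one expression matrix + design.

    Deterministic: every stage is a fixed function of the inputs and the
    config (no random state).  If ``config.output_dir`` is set, per-
    component selection TSVs and a JSON run report are written there.
    """
    config = config or PipelineConfig()
    with _stage("tensorize"):
        tensor = standardize(build_tensor(matrix, design))
    with _stage("hosvd"):
        decomposition = hosvd(tensor)
    with _stage("pattern_select"):
        l3, l4 = pattern_select.choose_auxiliary_components(decomposition)
        interesting = pattern_select.select_interesting_condition_components(
            decomposition, delta=config.delta, theta=config.theta
        )
    selections: list[ComponentSelection] = []
    with _stage("gene_select"):
        for l2, label in interesting:
            choice = pattern_select.choose_gene_component(
                decomposition, l2, l3, l4,
                search_limit=config.search_limit, pattern=label,
            )
            u = decomposition.gene_scores(choice.l1)
            result = gene_select.select_genes(
                u,
                component=choice.l1,
                grid=gene_select.default_sigma_grid(u, config.sigma_grid_size),
                n_bins=config.n_bins,
                alpha=config.alpha,
                gene_ids=decomposition.gene_ids,
            )
            selections.append(ComponentSelection(choice=choice, result=result))

    report = _build_report(tensor, decomposition, l3, l4, interesting, selections, config)
    out = PipelineResult(
        tensor=tensor, hosvd=decomposition, l3=l3, l4=l4,
        selections=selections, report=report,
    )
    if config.output_dir is not None:
        _write_outputs(out, config)
    return out


def _build_report(tensor, decomposition, l3, l4, interesting, selections, config):
    condition_factor = decomposition.condition_factor
    return {
        "n_genes": tensor.n_genes,
        "tensor_shape": list(tensor.shape),
        "n_observed_cells": tensor.n_observed,
        "parameters": {
            "alpha": config.alpha,
            "delta": config.delta,
            "theta": config.theta,
            "n_bins": config.n_bins,
            "sigma_grid_size": config.sigma_grid_size,
            "search_limit": config.search_limit,
        },
        "replicate_component": l3,
        "hour_component": l4,
        "condition_components": [
            {
                "l2": l2,
                "pattern": label.value,
                "vector": [round(v, 6) for v in condition_factor[:, l2 - 1]],
            }
            for l2, label in interesting
        ],
        "selections": [
            {
                "l1": sel.choice.l1,
                "l2": sel.choice.l2,
                "l3": sel.choice.l3,
                "l4": sel.choice.l4,
                "pattern": sel.choice.pattern.value,
                "g_value": sel.choice.g_value,
                "sigma_star": sel.result.sigma_star,
                "n_selected": sel.result.n_selected,
            }
            for sel in selections
        ],
    }


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sel in result.selections:
        r = sel.result
        table = SelectionTable(
            gene_ids=result.hosvd.gene_ids,
            component=r.component,
            u=r.u,
            p=r.p,
            p_adj=r.p_adj,
            selected=r.selected,
            alpha=r.alpha,
        )
        name = f"selection_l2-{sel.choice.l2}_l1-{sel.choice.l1}.tsv"
        write_selection(table, outdir / name)
    write_run_report(result.report, outdir / "run_report.json")


def overlap_counts(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Venn counts (only A, both, only B) of two gene sets."""
    set_a, set_b = set(set_a), set(set_b)
    both = set_a & set_b
    return (len(set_a - both), len(both), len(set_b - both))
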
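"""Synthetic sleep-deprivation expression data with planted ground truth.

Generates genes x samples matrices over a given sample design (the bundled
42-sample HC/SD/RS time course by default) with the statistical structure
the analysis assumes:

* per-gene baseline expression drawn from a wide Gaussian (units are
  irrelevant downstream — slice standardization removes them);
* i.i.d. Gaussian measurement noise;
* a small planted fraction of genes carrying condition-dependent offsets
  with one of the sleep-response shapes (effect e, in noise-SD units,
  random sign per gene, constant across replicates and hours):

    - not recovered:  HC 0, SD +-e, RS +-e   (same sign)
    - overshoot:      HC 0, SD +-e, RS -+e   (opposite sign)
    - recovered:      HC 0, SD +-e, RS 0

The returned truth table records each gene's pattern and sign so that
selection sensitivity and false-discovery proportion can be scored
exactly.  All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_design import ExpressionMatrix, SampleDesign, sleep_deprivation_design
from .pattern_select import PatternLabel

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "score_selection"]

# condition offsets (HC, SD, RS) per pattern, in units of the effect size
_PATTERN_SHAPES: dict[PatternLabel, tuple[float, float, float]] = {
    PatternLabel.ALTERED_NOT_RECOVERED: (0.0, 1.0, 1.0),
    PatternLabel.OVERSHOOT: (0.0, 1.0, -1.0),
    PatternLabel.ALTERED_RECOVERED: (0.0, 1.0, 0.0),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``planted`` lists (pattern, fraction of genes, effect size) triples;
    effect sizes are in units of ``noise_sd``.  Baseline per-gene means are
    N(baseline_mean, baseline_sd^2).  ``noise_df``, if set, swaps the
    Gaussian noise for scaled Student-t noise with that many degrees of
    freedom — a heavier-tailed stress option, off by default.
    ``hour_modulation``, if given, multiplies the planted offsets by a
    per-hour factor (length M); default None = constant over hours.
    """

    n_genes: int = 20_000
    design: SampleDesign = field(default_factory=sleep_deprivation_design)
    planted: list[tuple[PatternLabel, float, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0
    noise_df: float | None = None
    hour_modulation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        total = 0.0
        for pattern, frac, effect in self.planted:
            if PatternLabel(pattern) not in _PATTERN_SHAPES:
                raise ValueError(f"cannot plant pattern {pattern!r}")
            if not 0 <= frac:
                raise ValueError("planted fractions must be >= 0")
            if effect <= 0:
                raise ValueError("effect sizes must be positive")
            total += frac
        if total >= 1:
            raise ValueError("planted fractions must sum to < 1")
        if self.hour_modulation is not None:
            hm = np.asarray(self.hour_modulation, dtype=float)
            if hm.shape != (self.design.n_hours,):
                raise ValueError("hour_modulation must have length M")
            self.hour_modulation = hm


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene pattern label (None = null) and effect sign."""

    labels: list[PatternLabel | None]
    signs: np.ndarray
    seed: int

    def indices_of(self, pattern: PatternLabel) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab == pattern], dtype=int
        )

    @property
    def n_planted(self) -> int:
        return sum(lab is not None for lab in self.labels)


def score_selection(
    truth: "SyntheticTruth",
    pattern: PatternLabel,
    selected: np.ndarray,
) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of a selected gene set.

    Sensitivity is scored against the genes planted with ``pattern``.
    Only *null* genes count as false discoveries: the two headline
    patterns share variance under unbalanced designs, so genes planted
    with a different non-null pattern legitimately appear in both
    components' lists (the method reports overlapping lists by design).
    FDP of an empty selection is 0.
    """
    selected = set(np.asarray(selected, dtype=int).tolist())
    true_set = set(truth.indices_of(pattern).tolist())
    if not true_set:
        raise ValueError(f"no genes planted with pattern {pattern}")
    nulls = {i for i, lab in enumerate(truth.labels) if lab is None}
    sensitivity = len(selected & true_set) / len(true_set)
    fdp = len(selected & nulls) / len(selected) if selected else 0.0
    return sensitivity, fdp


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Draw one synthetic study from ``spec``.

    Gene i, sample s:  value = baseline_i + offset(pattern_i, condition_s)
    + noise, with noise ~ N(0, noise_sd^2).  Planted gene counts are
    round(fraction * n_genes), assigned to the lowest-index free genes in
    the order the patterns are listed (gene order carries no meaning).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    design = spec.design
    sample_ids = design.sample_ids

    labels: list[PatternLabel | None] = [None] * n
    offsets = np.zeros((n, 3))  # per-gene (HC, SD, RS) offset
    signs = np.zeros(n)
    cursor = 0
    for pattern, frac, effect in spec.planted:
        count = round(frac * n)
        shape = np.array(_PATTERN_SHAPES[PatternLabel(pattern)])
        gene_signs = rng.choice([-1.0, 1.0], size=count)
        for i, s in zip(range(cursor, cursor + count), gene_signs):
            labels[i] = PatternLabel(pattern)
            offsets[i] = s * effect * spec.noise_sd * shape
            signs[i] = s
        cursor += count

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    if spec.noise_df is None:
        noise = rng.normal(0.0, spec.noise_sd, size=(n, len(sample_ids)))
    else:
        scale = spec.noise_sd / np.sqrt(spec.noise_df / (spec.noise_df - 2))
        noise = rng.standard_t(spec.noise_df, size=(n, len(sample_ids))) * scale

    values = baseline[:, None] + noise
    for col, sid in enumerate(sample_ids):
        cond, _k, m = design.assignments[sid]
        mod = 1.0 if spec.hour_modulation is None else spec.hour_modulation[m - 1]
        values[:, col] += mod * offsets[:, int(cond) - 1]

    matrix = ExpressionMatrix(
        gene_ids=[f"gene{i:05d}" for i in range(n)],
        sample_ids=list(sample_ids),
        values=values,
    )
    return matrix, design, SyntheticTruth(labels=labels, signs=signs, seed=spec.seed)
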
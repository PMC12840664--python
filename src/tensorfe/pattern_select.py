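"""Selecting the components of interest from an HOSVD.

The study design asks three things of the non-gene singular value vectors:

* the condition vector u_{l2 j} over (HC, SD, RS) should be *informative* —
  distinct between control and the other conditions.  Its shape is
  classified into the sleep-biology patterns: altered in SD and recovered
  in RS; altered and *not* recovered; altered and *overshot* (RS crosses
  past baseline); or constant / other.
* the replicate vector u_{l3 k} should be as constant as possible
  (expression should not depend on the replicate);
* no time dependence is pre-judged, so the hour vector u_{l4 m} is likewise
  taken as the most constant one.

Given the chosen (l2, l3, l4), the gene component l1 is the one whose core
entry G(l1, l2, l3, l4) has the largest absolute value among the first
``search_limit`` gene components: the gene vector contributing most to the
selected condition pattern.

Classification thresholds: a vector (scaled to unit RMS) is *constant* if
no entry deviates from the mean by more than ``delta``; SD is *altered* if
|u_SD - u_HC| > delta; RS is judged *recovered* (close to HC), *not
recovered* (close to SD) or *overshot* (beyond HC, on the opposite side)
by comparing its deviations against ``theta`` times the SD alteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .decomposition import HosvdResult

__all__ = [
    "PatternLabel",
    "ComponentChoice",
    "classify_condition_vector",
    "constancy_score",
    "choose_auxiliary_components",
    "choose_gene_component",
    "select_interesting_condition_components",
]

DEFAULT_DELTA = 0.3
DEFAULT_THETA = 0.5
DEFAULT_SEARCH_LIMIT = 10


class PatternLabel(str, Enum):
    CONSTANT = "constant"
    ALTERED_RECOVERED = "altered_recovered"
    ALTERED_NOT_RECOVERED = "altered_not_recovered"
    OVERSHOOT = "overshoot"
    OTHER = "other"


@dataclass
class ComponentChoice:
    """A fully resolved (l1, l2, l3, l4) choice; indices are 1-based."""

    l1: int
    l2: int
    l3: int
    l4: int
    g_value: float
    pattern: PatternLabel


def classify_condition_vector(
    u: np.ndarray,
    delta: float = DEFAULT_DELTA,
    theta: float = DEFAULT_THETA,
) -> PatternLabel:
    """Label a 3-vector over (HC, SD, RS) with its sleep-response pattern.

    The vector is first scaled to unit RMS so thresholds are
    scale-invariant; labels are also invariant to a global sign flip,
    since only relative deviations from HC enter the rules.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ValueError("condition vector must have length 3 (HC, SD, RS)")
    rms = np.sqrt(np.mean(u**2))
    if rms == 0.0:
        raise ValueError("zero condition vector")
    if not (0 < delta < 1 and 0 < theta < 1):
        raise ValueError("delta and theta must lie in (0, 1)")
    u = u / rms
    if np.max(np.abs(u - u.mean())) <= delta:
        return PatternLabel.CONSTANT
    d_sd = u[1] - u[0]
    d_rs = u[2] - u[0]
    if abs(d_sd) > delta:
        if abs(d_rs) <= theta * abs(d_sd):
            return PatternLabel.ALTERED_RECOVERED
        if abs(u[2] - u[1]) <= theta * abs(d_sd):
            return PatternLabel.ALTERED_NOT_RECOVERED
        if np.sign(d_rs) == -np.sign(d_sd):
            return PatternLabel.OVERSHOOT
    return PatternLabel.OTHER


def constancy_score(u: np.ndarray) -> float:
    """How constant a vector is: |sum(u)| / (sqrt(K) * ||u||), in [0, 1].

    Equals the squared-cosine-root of the angle to the all-ones direction:
    1 for a constant vector, 0 for one summing to zero.  Scale-invariant.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0.0:
        raise ValueError("zero vector has no constancy score")
    return float(abs(u.sum()) / (np.sqrt(len(u)) * norm))


def _most_constant_column(factor: np.ndarray) -> int:
    scores = [constancy_score(factor[:, c]) for c in range(factor.shape[1])]
    return int(np.argmax(scores)) + 1  # argmax takes the first of ties


def choose_auxiliary_components(result: HosvdResult) -> tuple[int, int]:
    """Pick the replicate and hour components (l3, l4), 1-based.

    Both are the most-constant column of their factor (ties to the
    smallest index): replicates should not matter by design, and no hour
    dependence is imposed, so the flat component is preferred for both.
    """
    return (
        _most_constant_column(result.replicate_factor),
        _most_constant_column(result.hour_factor),
    )


def choose_gene_component(
    result: HosvdResult,
    l2: int,
    l3: int,
    l4: int,
    search_limit: int = DEFAULT_SEARCH_LIMIT,
    pattern: PatternLabel = PatternLabel.OTHER,
) -> ComponentChoice:
    """Pick l1 maximizing |G(l1, l2, l3, l4)| over l1 <= search_limit.

    Ties go to the smallest l1.  All indices 1-based.
    """
    if search_limit < 1:
        raise ValueError("search_limit must be >= 1")
    limit = min(search_limit, result.core.shape[0])
    fiber = result.core[:limit, l2 - 1, l3 - 1, l4 - 1]
    if np.all(fiber == 0.0):
        raise ValueError(
            f"core fiber at (l2={l2}, l3={l3}, l4={l4}) is all zero; "
            "no informative gene component"
        )
    l1 = int(np.argmax(np.abs(fiber))) + 1
    return ComponentChoice(
        l1=l1, l2=l2, l3=l3, l4=l4, g_value=float(fiber[l1 - 1]), pattern=pattern
    )


def select_interesting_condition_components(
    result: HosvdResult,
    delta: float = DEFAULT_DELTA,
    theta: float = DEFAULT_THETA,
) -> list[tuple[int, PatternLabel]]:
    """All condition components with a non-trivial pattern, in index order.

    Returns (l2, label) pairs, 1-based, excluding components classified as
    constant or other.

    Components whose entries all have one strict sign are also excluded:
    when missing cells are zero-filled and the design is unbalanced, the
    leading condition component is the overall-expression-level direction
    with entries weighted by per-condition occupancy rather than a flat
    vector, and a vector that never crosses the zero baseline contrasts
    nothing.  (Columns orthogonal to such a one-signed leading column
    necessarily change sign, so only baseline-like components are ever
    dropped by this rule.)
    """
    out = []
    factor = result.condition_factor
    for c in range(factor.shape[1]):
        u = factor[:, c]
        if u.min() > 0 or u.max() < 0:  # baseline-like: no zero crossing
            continue
        label = classify_condition_vector(u, delta=delta, theta=theta)
        if label not in (PatternLabel.CONSTANT, PatternLabel.OTHER):
            out.append((c + 1, label))
    return out
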
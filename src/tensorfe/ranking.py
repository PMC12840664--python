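"""Pseudocount log-ratio top-k ranking.

A small data-agnostic utility: given two non-negative per-gene signal maps
(e.g. predicted chromatin accessibility in two tissues), rank genes by

    score_g = ln( (numerator_g + pseudo) / (denominator_g + pseudo) )

and return the top k in the requested direction.  The pseudocount
(default 1e-6) keeps zero denominators finite; it is applied to the
numerator as well so that zero numerators also get finite scores.  The
log base is natural — any base gives the same ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping

logger = logging.getLogger(__name__)

__all__ = ["RankedList", "log_ratio_topk"]


@dataclass
class RankedList:
    """Genes ordered by log-ratio score, best first."""

    gene_ids: list[str]
    scores: list[float]
    direction: Literal["larger", "smaller"]
    k: int


def log_ratio_topk(
    numerator: Mapping[str, float],
    denominator: Mapping[str, float],
    k: int = 100,
    direction: Literal["larger", "smaller"] = "larger",
    pseudo: float = 1e-6,
) -> RankedList:
    """Top-k genes by pseudocount log ratio of two signal maps.

    Ties are broken by lexical gene-ID order; if k exceeds the gene count
    the full ranked list is returned with a warning.
    """
    if set(numerator) != set(denominator):
        only_n = set(numerator) - set(denominator)
        only_d = set(denominator) - set(numerator)
        raise ValueError(
            f"gene sets differ (only in numerator: {sorted(only_n)[:3]}, "
            f"only in denominator: {sorted(only_d)[:3]})"
        )
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("larger", "smaller"):
        raise ValueError("direction must be 'larger' or 'smaller'")
    bad = [g for g in numerator if numerator[g] < 0 or denominator[g] < 0]
    if bad:
        raise ValueError(f"negative values for genes {sorted(bad)[:3]}")
    scores = {
        g: math.log((numerator[g] + pseudo) / (denominator[g] + pseudo))
        for g in numerator
    }
    if k > len(scores):
        logger.warning(
            "k=%d exceeds gene count %d; returning the full list", k, len(scores)
        )
    reverse = direction == "larger"
    ordered = sorted(scores, key=lambda g: ((-scores[g]) if reverse else scores[g], g))
    top = ordered[: min(k, len(ordered))]
    return RankedList(
        gene_ids=top, scores=[scores[g] for g in top], direction=direction, k=k
    )
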
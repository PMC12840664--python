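"""Expression-table and sample-design I/O.

The analyses this package supports start from a genes x samples expression
table (tab-delimited text, stable gene IDs in the first column) together
with a *sample design*: a map assigning each sample column a condition
(home cage HC, sleep deprivation SD, recovery sleep RS), a replicate index
and an hour level.  The design determines which cells of the
gene x condition x replicate x hour tensor are observed; unassigned cells
are treated as missing and zero-filled downstream.

The module also carries the bundled sleep-deprivation time-course design:
42 samples occupying 42 of the 3 x 5 x 5 (condition, replicate, hour)
cells, with three-replicate groups occupying replicate slots 2..4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Condition",
    "ExpressionMatrix",
    "SampleDesign",
    "SelectionTable",
    "read_expression",
    "read_design",
    "write_design",
    "write_selection",
    "sleep_deprivation_design",
]


class Condition(IntEnum):
    """Experimental condition (tensor mode j)."""

    HC = 1  # home cage (control)
    SD = 2  # sleep deprivation
    RS = 3  # recovery sleep


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (already-normalized) expression values.

    Parameters
    ----------
    gene_ids
        Unique row identifiers, one per gene.
    sample_ids
        Unique column labels.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; all
        entries must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class SampleDesign:
    """Maps sample IDs to (condition, replicate, hour) tensor cells.

    ``assignments`` maps each sample column to a triple
    ``(condition, replicate, hour_index)`` with 1-based replicate and hour
    indices.  Every assigned triple must be unique: one sample per cell.
    ``n_replicates`` / ``n_hours`` declare the tensor mode sizes K and M,
    which may exceed the occupied range (missing cells are zero-filled
    downstream).
    """

    assignments: dict[str, tuple[Condition, int, int]]
    n_replicates: int
    n_hours: int
    hour_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int, int], str] = {}
        for sid, (cond, k, m) in self.assignments.items():
            cond = Condition(cond)
            if not 1 <= k <= self.n_replicates:
                raise ValueError(
                    f"sample {sid!r}: replicate {k} outside 1..{self.n_replicates}"
                )
            if not 1 <= m <= self.n_hours:
                raise ValueError(
                    f"sample {sid!r}: hour index {m} outside 1..{self.n_hours}"
                )
            cell = (int(cond), k, m)
            if cell in seen:
                raise ValueError(
                    f"samples {seen[cell]!r} and {sid!r} both assigned "
                    f"(condition={cond.name}, replicate={k}, hour={m})"
                )
            seen[cell] = sid
            self.assignments[sid] = (cond, k, m)

    @property
    def n_conditions(self) -> int:
        return 3

    @property
    def shape(self) -> tuple[int, int, int]:
        """Mode sizes (J, K, M) of the non-gene tensor modes."""
        return (self.n_conditions, self.n_replicates, self.n_hours)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def occupied_cells(self) -> set[tuple[int, int, int]]:
        """The set of observed (condition, replicate, hour) cells, 1-based."""
        return {(int(c), k, m) for c, k, m in self.assignments.values()}

    def condition_label(self, sample_id: str) -> str:
        cond, k, m = self.assignments[sample_id]
        hour = self.hour_labels.get(m, str(m))
        return f"{cond.name}{hour}"


@dataclass
class SelectionTable:
    """Per-gene selection results for one gene-mode component."""

    gene_ids: list[str]
    component: int  # gene-mode component index ell1, 1-based
    u: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    selected: np.ndarray
    alpha: float = 0.01

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("u", "p", "p_adj", "selected"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if not np.array_equal(self.selected, self.p_adj < self.alpha):
            raise ValueError("selected flag inconsistent with p_adj < alpha")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "component": self.component,
                "u": self.u,
                "p": self.p,
                "p_adj": self.p_adj,
                "selected": self.selected.astype(int),
            }
        )

    @property
    def selected_genes(self) -> set[str]:
        return {g for g, s in zip(self.gene_ids, self.selected) if s}


def read_expression(
    path: str | Path,
    *,
    sep: str = "\t",
    gene_id_column: int = 0,
    strict: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The default dialect is the GEO-supplementary-file style: tab-delimited,
    header row of sample labels, gene IDs in the first column.

    Raises
    ------
    ValueError
        On duplicate gene IDs, or (in strict mode) any non-numeric or
        missing cell, naming the offending gene and sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=gene_id_column)
    gene_ids = [str(g) for g in df.index]
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float)))
    if bad.size:
        i, j = bad[0]
        msg = (
            f"{path}: non-numeric or missing value {df.iat[i, j]!r} at "
            f"gene {gene_ids[i]!r}, sample {df.columns[j]!r}"
        )
        if strict:
            raise ValueError(msg)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(c) for c in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


_CONDITION_NAMES = {c.name: c for c in Condition}


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design from a YAML (or JSON) config file.

    Expected structure::

        n_replicates: 5
        n_hours: 5
        hour_labels: {1: "3", 2: "5", ...}      # optional
        samples:
          sample_A: {condition: HC, replicate: 2, hour: 1}
          ...
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return design_from_dict(cfg)


def design_from_dict(cfg: Mapping) -> SampleDesign:
    try:
        n_replicates = int(cfg["n_replicates"])
        n_hours = int(cfg["n_hours"])
        samples = cfg["samples"]
    except KeyError as e:
        raise ValueError(f"design config missing key: {e}") from None
    assignments = {}
    for sid, entry in samples.items():
        cond = entry["condition"]
        cond = _CONDITION_NAMES[cond] if isinstance(cond, str) else Condition(cond)
        assignments[str(sid)] = (cond, int(entry["replicate"]), int(entry["hour"]))
    hour_labels = {int(k): str(v) for k, v in (cfg.get("hour_labels") or {}).items()}
    return SampleDesign(
        assignments=assignments,
        n_replicates=n_replicates,
        n_hours=n_hours,
        hour_labels=hour_labels,
    )


def design_to_dict(design: SampleDesign) -> dict:
    return {
        "n_replicates": design.n_replicates,
        "n_hours": design.n_hours,
        "hour_labels": {k: v for k, v in sorted(design.hour_labels.items())},
        "samples": {
            sid: {"condition": cond.name, "replicate": k, "hour": m}
            for sid, (cond, k, m) in design.assignments.items()
        },
    }


def write_design(design: SampleDesign, path: str | Path) -> None:
    """Write a design config that :func:`read_design` round-trips exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def write_selection(table: SelectionTable, path: str | Path) -> None:
    """Write a selection table as TSV, one row per gene, input gene order."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_run_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")


# Occupancy of the bundled sleep-deprivation time-course design.  Hours are
# indexed m=1..5 = {3, 5, 6, 7, 12} h; three-replicate groups occupy
# replicate slots 2..4 of the five available.
_SLEEP_OCCUPANCY: list[tuple[Condition, int, range]] = [
    (Condition.HC, 1, range(2, 5)),
    (Condition.HC, 2, range(1, 6)),
    (Condition.HC, 3, range(1, 6)),
    (Condition.HC, 4, range(1, 6)),
    (Condition.HC, 5, range(1, 6)),
    (Condition.SD, 1, range(2, 5)),
    (Condition.SD, 2, range(1, 6)),
    (Condition.SD, 3, range(2, 5)),
    (Condition.RS, 2, range(1, 6)),
    (Condition.RS, 3, range(2, 5)),
]

_SLEEP_HOUR_LABELS = {1: "3", 2: "5", 3: "6", 4: "7", 5: "12"}


def sleep_deprivation_design() -> SampleDesign:
    """The bundled 42-sample HC/SD/RS time-course design.

    Occupies 42 of the 75 cells of the 3 x 5 x 5 (condition, replicate,
    hour) grid: HC at hours {3, 5, 6, 7, 12}, SD at {3, 5, 6}, RS at
    {2(RS hour label), 6}; hour-3 HC/SD and hour-6 SD/RS groups have three
    replicates in slots 2..4, the rest five.  Sample IDs follow the
    ``<condition><hour>_r<replicate>`` convention (e.g. ``SD5_r3``); anyone
    applying this design to a real accession table must map its column
    labels onto these cells.
    """
    labels = dict(_SLEEP_HOUR_LABELS)
    labels_rs = {**labels, 2: "2"}  # recovery hour 2 is labelled RS2
    assignments: dict[str, tuple[Condition, int, int]] = {}
    for cond, m, ks in _SLEEP_OCCUPANCY:
        hour = (labels_rs if cond is Condition.RS else labels)[m]
        for k in ks:
            assignments[f"{cond.name}{hour}_r{k}"] = (cond, k, m)
    return SampleDesign(
        assignments=assignments, n_replicates=5, n_hours=5, hour_labels=labels
    )
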
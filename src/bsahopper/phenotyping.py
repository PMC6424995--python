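"""Damage-score phenotyping: AUC summaries and extreme-pool selection.

Seedling damage from brown planthopper (BPH) infestation is scored daily on
the 1-9 SES scale and summarised per line as the area under the damage
progression curve (trapezoid rule), in score*days.  Lower AUC means more
resistant.  Lines at the two tails of the AUC distribution feed the
resistant/susceptible bulks for the QTL-seq scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "DamageSeries",
    "AUCRecord",
    "PoolAssignment",
    "auc_trapezoid",
    "auc_table",
    "average_auc",
    "line_summary",
    "select_extremes",
    "read_phenotypes",
    "write_phenotypes",
]


@dataclass(frozen=True)
class DamageSeries:
    """Ordered daily damage scores for one line x BPH population x replicate."""

    line_id: str
    population_id: str
    replicate: int
    scores: tuple = ()
    day_spacing: float = 1.0

    def __post_init__(self):
        scores = tuple(float(s) for s in self.scores)
        object.__setattr__(self, "scores", scores)
        if len(scores) < 2:
            raise DataError(
                f"DamageSeries for {self.line_id}/{self.population_id}: "
                f"need >= 2 daily scores, got {len(scores)} (AUC undefined)"
            )
        if any(s < 0 or s > 9 for s in scores):
            raise DataError(
                f"DamageSeries for {self.line_id}/{self.population_id}: "
                "scores must lie within [0, 9] (SES scale)"
            )
        if self.day_spacing <= 0:
            raise DataError("day_spacing must be > 0")


@dataclass(frozen=True)
class AUCRecord:
    line_id: str
    population_id: str
    auc: float
    n_days: int


@dataclass(frozen=True)
class PoolAssignment:
    """Disjoint resistant (low AUC) and susceptible (high AUC) line sets."""

    resistant: tuple
    susceptible: tuple


def auc_trapezoid(series: DamageSeries) -> AUCRecord:
    """Area under the damage curve by the trapezoid rule.

    For scores s_1..s_n at spacing h the AUC is
    sum_i (s_i + s_{i+1}) / 2 * h, i.e. a constant score of 9 over five
    days gives 36 score*days and over eight days gives 63.
    """
    scores = np.asarray(series.scores, dtype=float)
    auc = float(np.trapezoid(scores, dx=series.day_spacing))
    return AUCRecord(series.line_id, series.population_id, auc, len(scores))


def auc_table(serieses: Iterable[DamageSeries]) -> pd.DataFrame:
    """Per-replicate AUC table with columns line_id, population_id, replicate, auc."""
    rows = []
    for s in serieses:
        rec = auc_trapezoid(s)
        rows.append((s.line_id, s.population_id, s.replicate, rec.auc, rec.n_days))
    return pd.DataFrame(
        rows, columns=["line_id", "population_id", "replicate", "auc", "n_days"]
    )


def average_auc(records: Sequence[AUCRecord]) -> float:
    """Cross-population mean AUC for one line.

    Replicates are first averaged within each BPH population; the reported
    value is the unweighted arithmetic mean of the per-population means,
    so populations with unequal replicate counts carry equal weight.
    """
    if len(records) == 0:
        raise DataError("average_auc: need at least one AUCRecord")
    lines = {r.line_id for r in records}
    if len(lines) > 1:
        raise DataError(f"average_auc mixes lines: {sorted(lines)}")
    df = pd.DataFrame(
        [(r.population_id, r.auc) for r in records], columns=["population_id", "auc"]
    )
    per_pop = df.groupby("population_id")["auc"].mean()
    return float(per_pop.mean())


def line_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Line-level mean AUC from a per-replicate AUC table.

    Averages replicates within population, then populations within line.
    Returns columns line_id, mean_auc sorted by line_id.
    """
    per_pop = (
        table.groupby(["line_id", "population_id"])["auc"].mean().reset_index()
    )
    out = per_pop.groupby("line_id")["auc"].mean().rename("mean_auc").reset_index()
    return out.sort_values("line_id").reset_index(drop=True)


def select_extremes(
    auc_table: pd.DataFrame, n_resistant: int, n_susceptible: int
) -> PoolAssignment:
    """Pick the lowest-AUC lines as the resistant pool and the highest as the
    susceptible pool.

    ``auc_table`` needs columns ``line_id`` and ``mean_auc`` (one row per
    line).  Ties at a pool boundary are broken by ascending line_id, so
    membership is deterministic and invariant to input row order.
    """
    if n_resistant < 0 or n_susceptible < 0:
        raise DataError("pool sizes must be non-negative")
    n = len(auc_table)
    if n_resistant + n_susceptible > n:
        raise DataError(
            f"requested {n_resistant}+{n_susceptible} lines but only {n} available"
        )
    ordered = auc_table.sort_values(
        ["mean_auc", "line_id"], kind="mergesort"
    ).reset_index(drop=True)
    resistant = tuple(ordered["line_id"].iloc[:n_resistant])
    susceptible = tuple(
        auc_table.sort_values(
            ["mean_auc", "line_id"], ascending=[False, True], kind="mergesort"
        )["line_id"].iloc[:n_susceptible]
    )
    return PoolAssignment(resistant=resistant, susceptible=susceptible)


def write_phenotypes(path, serieses: Iterable[DamageSeries]) -> None:
    """TSV with header line,population,replicate,d1..dN."""
    serieses = list(serieses)
    if not serieses:
        raise DataError("no damage series to write")
    n_days = len(serieses[0].scores)
    if any(len(s.scores) != n_days for s in serieses):
        raise DataError("all series in one file must share n_days")
    cols = ["line", "population", "replicate"] + [f"d{i + 1}" for i in range(n_days)]
    rows = [
        [s.line_id, s.population_id, s.replicate, *s.scores] for s in serieses
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> list:
    """Read the phenotype TSV written by :func:`write_phenotypes`."""
    df = pd.read_csv(path, sep="\t")
    day_cols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    day_cols.sort(key=lambda c: int(c[1:]))
    if not day_cols:
        raise DataError(f"{path}: no daily score columns d1..dN found")
    return [
        DamageSeries(
            line_id=str(r["line"]),
            population_id=str(r["population"]),
            replicate=int(r["replicate"]),
            scores=tuple(float(r[c]) for c in day_cols),
        )
        for _, r in df.iterrows()
    ]
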
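"""Read, validate, aggregate and reshape AOI fixation-duration tables.

The canonical exchange format is a long UTF-8 TSV with header
``participant\ttask\taoi\ttdof_ms`` — one row per participant, task and Area
of Interest, holding the total duration of fixations (TDoF) in milliseconds.
A wide CSV dialect (``participant,task,<AOI1>,...,<AOID>``) is accepted as a
convenience. This module turns such exports into the strictly positive
:class:`~gazecoda.coda.CompositionMatrix` the analysis modules consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coda import CompositionMatrix, replace_zeros

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["participant", "task", "aoi", "tdof_ms"]

#: AOI labels of the seven-region segmentation used throughout the package's
#: example scenarios (order follows the segmentation figure convention).
STUDY_AOIS = ["Background", "Furniture", "Kids", "Maid", "Man", "Mother", "Wife"]

__all__ = ["AOITable", "DesignReport", "STUDY_AOIS", "aggregate_aois",
           "read_fixation_table", "to_composition_matrix", "validate_design",
           "write_fixation_table"]


@dataclass
class AOITable:
    """Long-format (participant, task, aoi, tdof_ms) records plus AOI order.

    Every (participant, task) pair present carries exactly one record per AOI
    in ``aoi_set``; records materialised as zeros during completion are
    listed in ``completed``.
    """

    data: pd.DataFrame
    aoi_set: list[str]
    completed: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"AOITable data lacks columns {missing}")
        df = df[LONG_COLUMNS].copy()
        df["tdof_ms"] = pd.to_numeric(df["tdof_ms"])
        if (df["tdof_ms"] < 0).any():
            bad = df.index[df["tdof_ms"] < 0].tolist()
            raise ValueError(f"negative tdof_ms at rows {bad}")
        dup = df.duplicated(subset=["participant", "task", "aoi"])
        if dup.any():
            raise ValueError(
                f"duplicate (participant, task, aoi) records at rows {df.index[dup].tolist()}"
            )
        unknown = set(df["aoi"]) - set(self.aoi_set)
        if unknown:
            raise ValueError(f"records reference AOIs outside aoi_set: {sorted(unknown)}")
        self.data = _complete_grid(df, self.aoi_set, self.completed)

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique().tolist())

    @property
    def tasks(self) -> list:
        return sorted(self.data["task"].unique().tolist())

    def wide(self) -> pd.DataFrame:
        """Pivot to one row per (participant, task), one column per AOI."""
        w = self.data.pivot_table(
            index=["participant", "task"], columns="aoi", values="tdof_ms", sort=False
        )
        return w[self.aoi_set].reset_index()


def _complete_grid(df: pd.DataFrame, aoi_set: list[str], completed: list) -> pd.DataFrame:
    """Materialise a zero record for every missing AOI of a present cell."""
    pairs = df[["participant", "task"]].drop_duplicates()
    full = pairs.merge(pd.DataFrame({"aoi": aoi_set}), how="cross")
    merged = full.merge(df, on=["participant", "task", "aoi"], how="left")
    added = merged["tdof_ms"].isna()
    if added.any():
        for _, r in merged.loc[added].iterrows():
            completed.append((r["participant"], r["task"], r["aoi"]))
        logger.warning("completed %d missing (participant, task, aoi) cells as zeros",
                       int(added.sum()))
        merged["tdof_ms"] = merged["tdof_ms"].fillna(0.0)
    cat = pd.Categorical(merged["aoi"], categories=aoi_set, ordered=True)
    merged = merged.assign(aoi=cat).sort_values(
        ["participant", "task", "aoi"], kind="stable"
    )
    merged["aoi"] = merged["aoi"].astype(str)
    return merged.reset_index(drop=True)


def read_fixation_table(path, dialect: str = "long", aoi_set: list[str] | None = None) -> AOITable:
    """Parse a fixation-duration export into an :class:`AOITable`.

    ``dialect='long'`` expects the canonical TSV; ``dialect='wide'`` a CSV
    with one column per AOI. Unknown columns in the long dialect are ignored
    with a warning; negative or unparseable durations are rejected.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path} lacks required columns {missing}")
        extra = [c for c in df.columns if c not in LONG_COLUMNS]
        if extra:
            logger.warning("ignoring unknown columns %s in %s", extra, path)
        try:
            df["tdof_ms"] = pd.to_numeric(df["tdof_ms"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable tdof_ms values in {path}: {exc}") from exc
        aois = aoi_set or list(dict.fromkeys(df["aoi"]))
    elif dialect == "wide":
        df = pd.read_csv(path)
        for c in ("participant", "task"):
            if c not in df.columns:
                raise ValueError(f"{path} lacks required column {c!r}")
        aois = aoi_set or [c for c in df.columns if c not in ("participant", "task")]
        df = df.melt(id_vars=["participant", "task"], value_vars=aois,
                     var_name="aoi", value_name="tdof_ms")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")
    table = AOITable(df[LONG_COLUMNS] if dialect == "long" else df, aois)
    logger.info("read %d records: %d participants x %d tasks x %d AOIs",
                len(table.data), len(table.participants), len(table.tasks),
                len(table.aoi_set))
    return table


def write_fixation_table(table: AOITable, path, dialect: str = "long") -> None:
    """Emit the canonical long TSV or the wide CSV dialect."""
    path = Path(path)
    if dialect == "long":
        table.data.to_csv(path, sep="\t", index=False)
    elif dialect == "wide":
        table.wide().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def aggregate_aois(table: AOITable, mapping: dict) -> AOITable:
    """Sum durations within AOI groups, e.g. the seven regions into
    {Visitor, Persons, Background}.

    ``mapping`` must cover every AOI; group order follows first appearance in
    the mapping's values. Aggregation conserves per-row totals exactly and is
    the preferred way to eliminate structural zeros in sparsely visited areas.
    """
    unmapped = [a for a in table.aoi_set if a not in mapping]
    if unmapped:
        raise ValueError(f"aoi mapping does not cover {unmapped}")
    groups = list(dict.fromkeys(mapping[a] for a in mapping))
    df = table.data.copy()
    df["aoi"] = df["aoi"].map(mapping)
    agg = df.groupby(["participant", "task", "aoi"], as_index=False, sort=False)[
        "tdof_ms"
    ].sum()
    return AOITable(agg, groups)


def to_composition_matrix(
    table: AOITable,
    tasks=None,
    zero_fraction: float = 0.65,
    kappa: float | None = None,
) -> CompositionMatrix:
    """One composition per (participant, task): the analysis-ready matrix.

    Rows with an all-zero duration vector are dropped with a warning (no
    relative information), remaining zeros are imputed at ``zero_fraction``
    of the column minimum positive value, and the result is optionally
    closed to ``kappa``.
    """
    wide = table.wide()
    if tasks is not None:
        wanted = set(np.atleast_1d(tasks).tolist())
        wide = wide[wide["task"].isin(wanted)].reset_index(drop=True)
    vals = wide[table.aoi_set].to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        dropped = wide.loc[totals == 0, ["participant", "task"]]
        logger.warning("dropping %d rows with zero total dwell time: %s",
                       len(dropped), dropped.to_dict("records"))
        wide = wide[totals > 0].reset_index(drop=True)
        vals = vals[totals > 0]
    vals, zero_log = replace_zeros(vals, zero_fraction, parts=table.aoi_set)
    if zero_log:
        logger.info("replaced %d zero cells at fraction %.2f of column minima",
                    len(zero_log), zero_fraction)
    from .coda import close  # local import avoids cycle at module load

    if kappa is not None:
        vals = close(vals, kappa)
    meta = wide[["participant", "task"]]
    return CompositionMatrix(vals, table.aoi_set, meta, kappa)


@dataclass
class DesignReport:
    """Completeness report for an expected participants x tasks grid."""

    n_participants: int
    n_tasks: int
    missing_cells: list[tuple]
    zero_counts: dict
    rows_per_task: dict
    merge_candidates: list[str]

    def __str__(self) -> str:  # human-readable summary for the CLI
        lines = [
            f"participants: {self.n_participants}",
            f"tasks: {self.n_tasks}",
            f"missing participant-task cells: {len(self.missing_cells)}",
        ]
        for cell in self.missing_cells[:20]:
            lines.append(f"  missing: {cell}")
        lines.append("zero cells per AOI: " + ", ".join(
            f"{a}={c}" for a, c in self.zero_counts.items()))
        lines.append("rows per task: " + ", ".join(
            f"{t}={c}" for t, c in self.rows_per_task.items()))
        if self.merge_candidates:
            lines.append("all-zero AOI within some task (merge candidates): "
                         + ", ".join(self.merge_candidates))
        return "\n".join(lines)


def validate_design(table: AOITable) -> DesignReport:
    """Report missing grid cells, zero counts per AOI and per-task row counts."""
    participants, tasks = table.participants, table.tasks
    present = set(map(tuple, table.data[["participant", "task"]].drop_duplicates().values))
    missing = [(p, t) for p in participants for t in tasks if (p, t) not in present]
    zero_counts = (
        table.data.assign(z=table.data["tdof_ms"] == 0)
        .groupby("aoi", sort=False)["z"].sum().astype(int).to_dict()
    )
    rows_per_task = (
        table.data.groupby("task")["participant"].nunique().to_dict()
    )
    merge = []
    for (task, aoi), grp in table.data.groupby(["task", "aoi"], sort=False):
        if (grp["tdof_ms"] == 0).all():
            merge.append(f"{aoi} (task {task})")
    return DesignReport(len(participants), len(tasks), missing, zero_counts,
                        rows_per_task, merge)
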
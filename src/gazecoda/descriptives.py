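"""Task-level descriptive summaries, compositional and classical side by side.

For each task the compositional track reports the closed geometric-mean
composition (in percent) and the variation matrix of pairwise log-ratios;
the classical track reports arithmetic means of the raw millisecond dwell
times and their Pearson correlation matrix. The mean-contrast log-ratio
ln(g_task / g_all) localises which AOIs drive a task away from the pooled
mean composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import (
    CompositionMatrix,
    VariationMatrix,
    close,
    compositional_mean,
    variation_matrix,
)

__all__ = ["TaskSummary", "mean_contrast_logratio", "summarize_tasks",
           "ternary_coordinates"]

#: ternary vertices: part 1 at the origin, part 2 right, part 3 top
_TERNARY_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass
class TaskSummary:
    task: object
    mean_composition: np.ndarray  # closed to 100
    arithmetic_means: np.ndarray  # raw ms
    variation: VariationMatrix
    correlation: np.ndarray
    n: int
    parts: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task": self.task,
                "aoi": self.parts,
                "mean_pct": self.mean_composition,
                "mean_ms": self.arithmetic_means,
            }
        )


def summarize_tasks(X: CompositionMatrix, ddof: int = 1) -> list[TaskSummary]:
    """One :class:`TaskSummary` per task found in ``X.row_meta``.

    Task subsets with fewer than two rows cannot support a variance and are
    skipped with a warning. Compositional statistics are computed on the
    (strictly positive) matrix values; arithmetic means and correlations on
    the same values interpreted as raw milliseconds.
    """
    import logging

    if X.row_meta is None or "task" not in X.row_meta.columns:
        raise ValueError("summarize_tasks needs row_meta with a 'task' column")
    out = []
    for task in pd.unique(X.row_meta["task"]):
        sub = X.subset((X.row_meta["task"] == task).to_numpy())
        if sub.n < 2:
            logging.getLogger(__name__).warning(
                "task %r has n=%d < 2 rows; skipped", task, sub.n)
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub.values, rowvar=False)
        out.append(
            TaskSummary(
                task=task,
                mean_composition=compositional_mean(sub, kappa=100.0),
                arithmetic_means=sub.values.mean(axis=0),
                variation=variation_matrix(sub, ddof=ddof),
                correlation=corr,
                n=sub.n,
                parts=X.parts,
            )
        )
    return out


def ternary_coordinates(X) -> np.ndarray:
    """Barycentric planar coordinates for three-part compositions.

    Each closed row (a, b, c) maps to a*A + b*B + c*C with vertices
    A=(0,0), B=(1,0), C=(0.5, sqrt(3)/2); the uniform composition lands on
    the centroid. Rescaling a row does not move its point.
    """
    vals = X.values if isinstance(X, CompositionMatrix) else np.atleast_2d(
        np.asarray(X, dtype=float))
    if vals.shape[-1] != 3:
        raise ValueError(f"ternary diagrams need exactly 3 parts, got {vals.shape[-1]}")
    shares = close(vals, 1.0)
    return shares @ _TERNARY_VERTICES


def mean_contrast_logratio(task_means, overall_mean, parts=None) -> pd.DataFrame:
    """Per-task, per-AOI log-ratio of the task mean share to the pooled mean share.

    Both means are closed to unit sum before the ratio, so the contrast is
    independent of the closure constant of the inputs. Values near zero mean
    the task's mean composition agrees with the pooled one for that AOI; a
    value of 1 means the task share is e-fold the pooled share.
    """
    overall = close(np.asarray(overall_mean, dtype=float), 1.0)
    rows = {}
    for task, mean in task_means.items():
        m = np.asarray(mean, dtype=float)
        if m.shape != overall.shape:
            raise ValueError(
                f"task {task!r} mean has {m.shape[-1]} parts, overall has {overall.shape[-1]}")
        rows[task] = np.log(close(m, 1.0) / overall)
    df = pd.DataFrame.from_dict(rows, orient="index")
    if parts is not None:
        df.columns = list(parts)
    df.index.name = "task"
    return df
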
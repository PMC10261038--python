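"""Per-peak differential metabolite analysis with BH-FDR control.

For each hybrid the pipeline tests every non-IS peak against each parent on
the log2 scale (two-sample Student's t), adjusts p-values by the
Benjamini-Hochberg step-up within the family of peaks of that comparison, and
calls a metabolite changed "compared with both parents" only when both parent
comparisons are significant in the same direction. Effect size is reported as
the log2 fold change of the hybrid mean over the mid-parent value, computed
on linear-scale abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vigormet._stats import students_t_test
from vigormet.preprocess import MetaboliteMatrix

__all__ = [
    "bh_fdr",
    "per_peak_tests",
    "log2fc_vs_mpv",
    "call_vs_both_parents",
    "differential_table",
    "heatmap_table",
    "HeatmapTable",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q(i) = min over j >= i (in the sorted order) of p(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def per_peak_tests(
    matrix: MetaboliteMatrix, group_a: str, group_b: str, *, welch: bool = False
) -> pd.Series:
    """Two-sample t-test p-value per non-IS peak between two lines.

    Expects a log2-scale matrix; peaks with zero pooled variance and equal
    means get p = 1.
    """
    if matrix.scale != "log2":
        raise ValueError("per_peak_tests expects a log2-scale matrix")
    for line in (group_a, group_b):
        if not matrix.columns_for(line):
            raise ValueError(f"line {line!r} absent from matrix")
    cols_a = matrix.columns_for(group_a)
    cols_b = matrix.columns_for(group_b)
    keep = ~matrix.peaks["is_internal_standard"].to_numpy(dtype=bool)
    p = {}
    for peak_id in matrix.data.index[keep]:
        a = matrix.data.loc[peak_id, cols_a].to_numpy(dtype=float)
        b = matrix.data.loc[peak_id, cols_b].to_numpy(dtype=float)
        p[peak_id] = students_t_test(a, b, welch=welch).p
    return pd.Series(p, name=f"p[{group_a} vs {group_b}]")


def log2fc_vs_mpv(hybrid_mean: float, parent1_mean: float, parent2_mean: float) -> float:
    """log2 of the hybrid abundance over the mid-parent abundance (linear scale)."""
    for value in (hybrid_mean, parent1_mean, parent2_mean):
        if not value > 0:
            raise ValueError("means must be positive on the linear scale")
    return float(np.log2(hybrid_mean / ((parent1_mean + parent2_mean) / 2.0)))


def call_vs_both_parents(
    q_vs_p1: float, dir_vs_p1: str, q_vs_p2: float, dir_vs_p2: str, threshold: float = 0.05
) -> str:
    """"up"/"down" only when both parent comparisons agree at q < threshold."""
    if q_vs_p1 < threshold and q_vs_p2 < threshold and dir_vs_p1 == dir_vs_p2 != "ns":
        return dir_vs_p1
    return "ns"


def _direction(delta: float, significant: bool) -> str:
    if not significant:
        return "ns"
    return "up" if delta > 0 else "down"


def differential_table(
    matrix: MetaboliteMatrix,
    hybrid: str,
    parent1: str,
    parent2: str,
    fdr: float = 0.05,
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Full per-peak differential table for one hybrid against its parents.

    BH adjustment is applied separately within each hybrid-vs-parent family
    of peaks. ``log2fc_vs_mpv`` back-transforms the log2 matrix to linear
    abundances before averaging; the difference-of-log2-means alternative is
    reported alongside as ``log2fc_vs_mpv_logmeans``.
    """
    p_vs = {}
    for parent in (parent1, parent2):
        p_vs[parent] = per_peak_tests(matrix, hybrid, parent, welch=welch)
    q_vs = {parent: pd.Series(bh_fdr(p), index=p.index) for parent, p in p_vs.items()}

    linear = np.power(2.0, matrix.data.loc[p_vs[parent1].index])
    means = {
        line: linear[matrix.columns_for(line)].mean(axis=1)
        for line in (hybrid, parent1, parent2)
    }
    log2_means = {
        line: matrix.data.loc[p_vs[parent1].index, matrix.columns_for(line)].mean(axis=1)
        for line in (hybrid, parent1, parent2)
    }

    rows = []
    for peak_id in p_vs[parent1].index:
        dirs = {}
        for parent in (parent1, parent2):
            sig = q_vs[parent][peak_id] < fdr
            dirs[parent] = _direction(means[hybrid][peak_id] - means[parent][peak_id], sig)
        rows.append(
            {
                "peak_id": peak_id,
                "annotation": matrix.peaks.loc[peak_id, "annotation"],
                "hybrid": hybrid,
                "p_vs_parent1": p_vs[parent1][peak_id],
                "q_vs_parent1": q_vs[parent1][peak_id],
                "dir_vs_parent1": dirs[parent1],
                "p_vs_parent2": p_vs[parent2][peak_id],
                "q_vs_parent2": q_vs[parent2][peak_id],
                "dir_vs_parent2": dirs[parent2],
                "log2fc_vs_mpv": log2fc_vs_mpv(
                    means[hybrid][peak_id], means[parent1][peak_id], means[parent2][peak_id]
                ),
                "log2fc_vs_mpv_logmeans": float(
                    log2_means[hybrid][peak_id]
                    - (log2_means[parent1][peak_id] + log2_means[parent2][peak_id]) / 2.0
                ),
                "call_vs_both_parents": call_vs_both_parents(
                    q_vs[parent1][peak_id],
                    dirs[parent1],
                    q_vs[parent2][peak_id],
                    dirs[parent2],
                    threshold=fdr,
                ),
            }
        )
    return pd.DataFrame(rows).set_index("peak_id")


@dataclass
class HeatmapTable:
    """Peaks x hybrids fold-change table with significance marks.

    ``values`` holds log2 fold changes vs MPV (NaN where a peak was not
    detected for that combination — rendered "ND"); ``marks`` is True where
    the peak was called changed vs both parents.
    """

    values: pd.DataFrame
    marks: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        def cell(value, mark):
            if pd.isna(value):
                return "ND"
            return f"{value:.2f}{'*' if mark else ''}"

        return pd.DataFrame(
            {
                col: [cell(v, m) for v, m in zip(self.values[col], self.marks[col])]
                for col in self.values.columns
            },
            index=self.values.index,
        )


def heatmap_table(tables: dict[str, pd.DataFrame]) -> HeatmapTable:
    """Combine per-hybrid differential tables into one fold-change matrix.

    ``tables`` maps a hybrid label to its :func:`differential_table` output.
    Peaks absent from a hybrid's table are ND for that column.
    """
    if not tables:
        raise ValueError("at least one differential table required")
    all_peaks: list[str] = []
    for table in tables.values():
        for peak in table.index:
            if peak not in all_peaks:
                all_peaks.append(peak)
    values = pd.DataFrame(index=pd.Index(all_peaks, name="peak_id"), columns=list(tables), dtype=float)
    marks = pd.DataFrame(False, index=values.index, columns=values.columns)
    for label, table in tables.items():
        values.loc[table.index, label] = table["log2fc_vs_mpv"]
        marks.loc[table.index, label] = (table["call_vs_both_parents"] != "ns").to_numpy()
    return HeatmapTable(values=values, marks=marks)
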
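"""Fumarate/malate ratio analysis with ANOVA and Tukey letter groups.

The fumarate/malate ratio is computed per sample on linear-scale (pre-log)
peak areas, summarised per line, and each hybrid's mean ratio is expressed as
a fold over the mid-parent ratio (the average of the two parental mean
ratios). Group differences are assessed by one-way ANOVA followed by Tukey's
HSD, summarised as a compact letter display: lines share a letter iff they
are not significantly different at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from vigormet.preprocess import MetaboliteMatrix

__all__ = [
    "sample_ratio",
    "ratio_table",
    "fold_vs_mpv_ratio",
    "mpv_area_ratio_fold",
    "anova_tukey",
    "AnovaTukeyResult",
    "RatioResult",
    "analyze_ratios",
]


def sample_ratio(fumarate_area: float, malate_area: float) -> float:
    """Fumarate over malate peak area for one sample (linear scale)."""
    if malate_area is None or not malate_area > 0:
        raise ValueError("malate area must be positive")
    if fumarate_area is None or np.isnan(fumarate_area):
        warnings.warn("fumarate area missing; ratio is missing", stacklevel=2)
        return float("nan")
    if fumarate_area <= 0:
        raise ValueError("fumarate area must be positive when present")
    return float(fumarate_area / malate_area)


def ratio_table(
    matrix: MetaboliteMatrix, fumarate_peak: str, malate_peak: str
) -> pd.DataFrame:
    """Per-sample fumarate/malate ratios with line metadata."""
    if matrix.scale != "linear":
        raise ValueError("ratios are computed on linear-scale areas (pre-log)")
    for peak in (fumarate_peak, malate_peak):
        if peak not in matrix.data.index:
            raise ValueError(f"peak {peak!r} absent from matrix")
    meta = matrix.samples
    ratios = [
        sample_ratio(matrix.data.loc[fumarate_peak, s], matrix.data.loc[malate_peak, s])
        for s in matrix.data.columns
    ]
    return meta.assign(ratio=ratios)


def fold_vs_mpv_ratio(hybrid_ratios, parent1_ratios, parent2_ratios) -> float:
    """Hybrid mean ratio over the mid-parent ratio.

    The mid-parent ratio is the average of the two parental *mean ratios*
    (ratios are averaged per line first, not rebuilt from mean areas).
    """
    h = np.asarray(hybrid_ratios, dtype=float)
    p1 = np.asarray(parent1_ratios, dtype=float)
    p2 = np.asarray(parent2_ratios, dtype=float)
    if min(h.size, p1.size, p2.size) < 2:
        raise ValueError("at least 2 samples per line required")
    mpv = (p1.mean() + p2.mean()) / 2.0
    if mpv <= 0:
        raise ValueError("mid-parent ratio must be positive")
    return float(h.mean() / mpv)


def mpv_area_ratio_fold(
    matrix: MetaboliteMatrix,
    fumarate_peak: str,
    malate_peak: str,
    hybrid: str,
    parent1: str,
    parent2: str,
) -> float:
    """Alternative convention: hybrid mean ratio over MPV-fumarate / MPV-malate.

    The mid-parent ratio here is the ratio of the mid-parent mean areas,
    rather than the mid-parent of the per-line mean ratios.
    """
    table = ratio_table(matrix, fumarate_peak, malate_peak)
    h = table.loc[table["line_id"] == hybrid, "ratio"].mean()

    def mean_area(peak: str, line: str) -> float:
        return float(matrix.data.loc[peak, matrix.columns_for(line)].mean())

    mpv_fum = (mean_area(fumarate_peak, parent1) + mean_area(fumarate_peak, parent2)) / 2.0
    mpv_mal = (mean_area(malate_peak, parent1) + mean_area(malate_peak, parent2)) / 2.0
    return float(h / (mpv_fum / mpv_mal))


@dataclass
class AnovaTukeyResult:
    anova_p: float
    letters: dict[str, str]
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj, reject


def _compact_letter_display(
    groups: list[str], means: dict[str, float], significant: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Letter columns start as the full group set; each significant pair splits
    every column containing both members; columns that are subsets of another
    are absorbed. Letters are assigned in descending order of group mean.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    columns: list[set] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        new_columns: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb duplicates and subsets
        unique: list[set] = []
        for col in new_columns:
            if col and col not in unique:
                unique.append(col)
        columns = [c for c in unique if not any(c < other for other in unique)]
    # deterministic column order: by first (highest-mean) member
    def column_key(col: set) -> tuple:
        ranks = sorted(order.index(g) for g in col)
        return tuple(ranks)

    columns.sort(key=column_key)
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, col in zip(alphabet, columns):
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons and letter groups."""
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = {name: np.asarray(v, dtype=float) for name, v in groups.items()}
    for name, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * arrays[name].size for name in arrays])

    if np.ptp(values) == 0:
        # all observations identical: no evidence of any difference
        names = list(arrays)
        pairwise = pd.DataFrame(
            [
                {"group1": a, "group2": b, "p_adj": 1.0, "reject": False}
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            ]
        )
        return AnovaTukeyResult(1.0, {name: "a" for name in names}, pairwise)

    anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    summary = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "group1": summary["group1"].astype(str),
            "group2": summary["group2"].astype(str),
            "p_adj": np.asarray(tukey.pvalues, dtype=float),
            "reject": np.asarray(tukey.reject, dtype=bool),
        }
    )
    significant = {
        frozenset((row.group1, row.group2)) for row in pairwise.itertuples() if row.reject
    }
    means = {name: float(v.mean()) for name, v in arrays.items()}
    letters = _compact_letter_display(list(arrays), means, significant)
    return AnovaTukeyResult(anova_p, letters, pairwise)


@dataclass
class RatioResult:
    combination_id: str
    per_sample: pd.DataFrame  # sample, line_id, replicate, ratio
    line_means: dict[str, float]
    mpv_ratio: float
    fold_vs_mpv: dict[str, float]  # per hybrid, mean-of-ratios convention
    fold_vs_mpv_area_convention: dict[str, float]
    anova_p: float
    tukey_letters: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for line, mean in self.line_means.items():
            rows.append(
                {
                    "combination_id": self.combination_id,
                    "line_id": line,
                    "mean_ratio": mean,
                    "mpv_ratio": self.mpv_ratio,
                    "fold_vs_mpv": self.fold_vs_mpv.get(line, np.nan),
                    "fold_vs_mpv_area_convention": self.fold_vs_mpv_area_convention.get(
                        line, np.nan
                    ),
                    "tukey_letter": self.tukey_letters[line],
                    "anova_p": self.anova_p,
                }
            )
        return pd.DataFrame(rows)


def analyze_ratios(
    matrix: MetaboliteMatrix,
    fumarate_peak: str,
    malate_peak: str,
    parents: tuple[str, str],
    hybrids: tuple[str, ...],
    alpha: float = 0.05,
    combination_id: str | None = None,
) -> RatioResult:
    """Complete fumarate/malate ratio analysis for one combination."""
    table = ratio_table(matrix, fumarate_peak, malate_peak)
    groups = {
        line: table.loc[table["line_id"] == line, "ratio"].to_numpy()
        for line in table["line_id"].unique()
    }
    p1, p2 = parents
    line_means = {line: float(v.mean()) for line, v in groups.items()}
    mpv_ratio = (line_means[p1] + line_means[p2]) / 2.0
    fold = {
        h: fold_vs_mpv_ratio(groups[h], groups[p1], groups[p2]) for h in hybrids
    }
    fold_area = {
        h: mpv_area_ratio_fold(matrix, fumarate_peak, malate_peak, h, p1, p2)
        for h in hybrids
    }
    res = anova_tukey(groups, alpha=alpha)
    return RatioResult(
        combination_id=combination_id or "+".join(parents),
        per_sample=table.reset_index(),
        line_means=line_means,
        mpv_ratio=mpv_ratio,
        fold_vs_mpv=fold,
        fold_vs_mpv_area_convention=fold_area,
        anova_p=res.anova_p,
        tukey_letters=res.letters,
    )
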
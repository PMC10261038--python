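"""Mid-parent / better-parent heterosis statistics and the four-class rule.

For a reciprocal cross (parent1, parent2, F1 = parent1 x parent2, F1rec =
parent2 x parent1) the mid-parent value (MPV) is the arithmetic mean of the
two parental trait means and the better-parent value (BPV) is the larger
parental mean. Heterosis of a hybrid is reported as the percentage of its
mean above a reference: BPH (over BPV) and MPH (over MPV).

A combination is classified from the two reciprocal hybrids, each tested
against the better parent's replicates with a two-sided Student's t-test:

* ``unclassifiable`` — the reciprocals trend in opposite significant
  directions (or any mixed pattern not matching the rules below);
* ``high`` — both reciprocals significantly exceed the BPV and at least one
  is >= 10% above it;
* ``weak`` — both reciprocals sit between 0 and 10% above the BPV with at
  least one significantly above;
* ``none`` — neither reciprocal is significantly above the BPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vigormet._stats import TTestResult, students_t_test

__all__ = [
    "ROLES",
    "BPVResult",
    "BPVTest",
    "HybridStats",
    "HeterosisResult",
    "compute_mpv",
    "compute_bpv",
    "heterosis_percent",
    "test_vs_bpv",
    "classify_combination",
    "evaluate_combination",
    "summarize_population",
]

ROLES = ("parent1", "parent2", "F1", "F1rec")
CLASS_LABELS = ("high", "weak", "none", "unclassifiable")


def compute_mpv(parent1_values, parent2_values) -> float:
    """Arithmetic mean of the two parental trait means."""
    p1 = np.asarray(parent1_values, dtype=float)
    p2 = np.asarray(parent2_values, dtype=float)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("both parental groups must be nonempty")
    return float((p1.mean() + p2.mean()) / 2.0)


@dataclass(frozen=True)
class BPVResult:
    bpv: float
    better_parent: str  # "parent1" | "parent2"
    tie: bool = False


def compute_bpv(parent1_values, parent2_values) -> BPVResult:
    """Larger parental mean and the role holding it (parent1 wins ties)."""
    p1 = np.asarray(parent1_values, dtype=float)
    p2 = np.asarray(parent2_values, dtype=float)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("both parental groups must be nonempty")
    m1, m2 = p1.mean(), p2.mean()
    if m1 == m2:
        return BPVResult(float(m1), "parent1", tie=True)
    if m1 > m2:
        return BPVResult(float(m1), "parent1")
    return BPVResult(float(m2), "parent2")


def heterosis_percent(f1_mean: float, reference: float) -> float:
    """Percent of the hybrid mean above a reference value (MPV or BPV)."""
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return float(100.0 * (f1_mean - reference) / reference)


@dataclass(frozen=True)
class BPVTest:
    p: float
    significant_above: bool
    significant_below: bool
    degenerate: bool = False


def test_vs_bpv(f1_values, better_parent_values, alpha: float = 0.05, *, welch: bool = False) -> BPVTest:
    """Two-sided t-test of a hybrid against the better parent's replicates.

    Direction flags are post-hoc: ``significant_above`` requires p < alpha
    and the hybrid mean above the better-parent mean, and symmetrically for
    ``significant_below``.
    """
    f1 = np.asarray(f1_values, dtype=float)
    bp = np.asarray(better_parent_values, dtype=float)
    res: TTestResult = students_t_test(f1, bp, welch=welch)
    above = bool(res.p < alpha and f1.mean() > bp.mean())
    below = bool(res.p < alpha and f1.mean() < bp.mean())
    return BPVTest(res.p, above, below, degenerate=res.degenerate)


@dataclass(frozen=True)
class HybridStats:
    """Per-hybrid summary used by the classification rule."""

    line_id: str
    mean: float
    bph_pct: float
    mph_pct: float
    p_vs_bpv: float
    significant_above: bool
    significant_below: bool


def classify_combination(
    f1: HybridStats, f1rec: HybridStats, bph_threshold: float = 10.0
) -> str:
    """Four-class heterosis label from the two reciprocal hybrids.

    Rules are evaluated in order; the first match wins. Mixed patterns
    outside the verbal taxonomy (e.g. one reciprocal strongly above BPV, the
    other nonsignificantly below) fall through to ``unclassifiable``.
    """
    if f1 is None or f1rec is None:
        raise ValueError("both reciprocal hybrids are required")
    bph = (f1.bph_pct, f1rec.bph_pct)
    sig_above = (f1.significant_above, f1rec.significant_above)
    sig_below = (f1.significant_below, f1rec.significant_below)
    if (sig_above[0] and sig_below[1]) or (sig_above[1] and sig_below[0]):
        return "unclassifiable"
    if all(sig_above) and max(bph) >= bph_threshold:
        return "high"
    if any(sig_above) and min(bph) >= 0 and max(bph) < bph_threshold:
        return "weak"
    if not any(sig_above):
        return "none"
    return "unclassifiable"


@dataclass
class HeterosisResult:
    combination_id: str
    mpv: float
    bpv: float
    better_parent: str
    parental_tie: bool
    hybrids: dict[str, HybridStats]  # keyed by role "F1" / "F1rec"
    class_label: str
    alpha: float = 0.05
    bph_threshold: float = 10.0
    degenerate: bool = field(default=False)

    def to_row(self) -> dict:
        row: dict = {
            "combination_id": self.combination_id,
            "mpv": self.mpv,
            "bpv": self.bpv,
            "better_parent": self.better_parent,
            "class_label": self.class_label,
        }
        for role, h in self.hybrids.items():
            row.update(
                {
                    f"{role}_line": h.line_id,
                    f"{role}_mean": h.mean,
                    f"{role}_bph_pct": h.bph_pct,
                    f"{role}_mph_pct": h.mph_pct,
                    f"{role}_p_vs_bpv": h.p_vs_bpv,
                    f"{role}_significant_above": h.significant_above,
                    f"{role}_significant_below": h.significant_below,
                }
            )
        return row


def _role_values(table: pd.DataFrame, role: str) -> np.ndarray:
    values = table.loc[table["role"] == role, "value"].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError(f"role {role!r} needs at least 2 replicates")
    return values


def evaluate_combination(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bph_threshold: float = 10.0,
    *,
    welch: bool = False,
) -> HeterosisResult:
    """Full heterosis evaluation of one combination's replicate-level table.

    ``table`` holds one combination with columns ``combination_id``,
    ``line_id``, ``role`` (parent1/parent2/F1/F1rec), ``replicate`` and
    ``value`` (e.g. mg fresh weight at 15 days after sowing).
    """
    combos = table["combination_id"].unique()
    if len(combos) != 1:
        raise ValueError("evaluate_combination expects exactly one combination")
    missing = set(ROLES) - set(table["role"])
    if missing:
        raise ValueError(f"combination {combos[0]!r} missing role(s): {sorted(missing)}")
    if (table["value"] <= 0).any():
        raise ValueError("trait values must be positive")

    p1 = _role_values(table, "parent1")
    p2 = _role_values(table, "parent2")
    mpv = compute_mpv(p1, p2)
    bp = compute_bpv(p1, p2)
    bp_values = p1 if bp.better_parent == "parent1" else p2

    hybrids: dict[str, HybridStats] = {}
    degenerate = False
    for role in ("F1", "F1rec"):
        values = _role_values(table, role)
        line_id = table.loc[table["role"] == role, "line_id"].iloc[0]
        t = test_vs_bpv(values, bp_values, alpha=alpha, welch=welch)
        degenerate = degenerate or t.degenerate
        hybrids[role] = HybridStats(
            line_id=str(line_id),
            mean=float(values.mean()),
            bph_pct=heterosis_percent(values.mean(), bp.bpv),
            mph_pct=heterosis_percent(values.mean(), mpv),
            p_vs_bpv=t.p,
            significant_above=t.significant_above,
            significant_below=t.significant_below,
        )

    label = classify_combination(hybrids["F1"], hybrids["F1rec"], bph_threshold)
    return HeterosisResult(
        combination_id=str(combos[0]),
        mpv=mpv,
        bpv=bp.bpv,
        better_parent=bp.better_parent,
        parental_tie=bp.tie,
        hybrids=hybrids,
        class_label=label,
        alpha=alpha,
        bph_threshold=bph_threshold,
        degenerate=degenerate,
    )


def summarize_population(results: list[HeterosisResult]) -> pd.DataFrame:
    """Class counts, percentage of total and BPH range per heterosis class."""
    if not results:
        raise ValueError("at least one combination required")
    total = len(results)
    rows = []
    for label in CLASS_LABELS:
        members = [r for r in results if r.class_label == label]
        bph = [h.bph_pct for r in members for h in r.hybrids.values()]
        rows.append(
            {
                "class_label": label,
                "count": len(members),
                "pct_of_total": 100.0 * len(members) / total,
                "bph_min": min(bph) if bph else np.nan,
                "bph_max": max(bph) if bph else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class_label")
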
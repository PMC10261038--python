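"""Germination timing and seed-area screening.

Germination time is summarised by t50: the hours-after-sowing (HAS) at which
half of the sown seeds show fully opened cotyledons. Sowing offsets computed
from per-line t50 values let an experimenter synchronise the germination
instant across lines, so that biomass comparisons at a fixed number of days
after sowing compare seedlings at the same developmental age.

Seed-area screening removes accessions whose seeds are significantly larger
than a control line, because seed-size differences confound biomass heterosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from vigormet._stats import students_t_test

__all__ = [
    "GerminationCourse",
    "T50Estimate",
    "estimate_t50",
    "sowing_offsets",
    "seed_area_screen",
]


@dataclass
class GerminationCourse:
    """Cumulative fraction of germinated seeds versus hours after sowing.

    ``fractions[i]`` is the cumulative fraction of seeds with fully opened
    cotyledons at ``times[i]`` HAS. Times must be strictly increasing and the
    fractions nondecreasing within [0, 1].
    """

    line_id: str
    times: np.ndarray
    fractions: np.ndarray
    warning: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.size != self.fractions.size:
            raise ValueError("times and fractions must have equal length")
        if self.times.size == 0:
            raise ValueError("empty germination course")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(self.fractions) < -1e-12):
            raise ValueError("fractions must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"line_id": self.line_id, "time_has": self.times, "fraction": self.fractions}
        )


@dataclass(frozen=True)
class T50Estimate:
    """t50 with an explicit status; ``t50`` is NaN when the line never reaches 50%."""

    line_id: str
    t50: float
    status: str  # "ok" | "not_germinated"
    method: str = "linear-interpolation"

    def __float__(self) -> float:
        return self.t50


def estimate_t50(course: GerminationCourse) -> T50Estimate:
    """Time at which the cumulative germination curve first crosses 50%.

    Linear interpolation between the two observations straddling 0.5; the
    first crossing wins if the curve touches 0.5 repeatedly. If the very
    first observation is already >= 0.5 the first observation time is
    returned. A curve that never reaches 0.5 yields status
    ``"not_germinated"`` and a NaN estimate.
    """
    above = np.nonzero(course.fractions >= 0.5)[0]
    if above.size == 0:
        return T50Estimate(course.line_id, float("nan"), "not_germinated")
    i = int(above[0])
    if i == 0:
        return T50Estimate(course.line_id, float(course.times[0]), "ok")
    t0, t1 = course.times[i - 1], course.times[i]
    f0, f1 = course.fractions[i - 1], course.fractions[i]
    t50 = t0 + (t1 - t0) * (0.5 - f0) / (f1 - f0)
    return T50Estimate(course.line_id, float(t50), "ok")


def sowing_offsets(t50_by_line: Mapping[str, float]) -> dict[str, float]:
    """Per-line sowing delays (hours) that align expected germination instants.

    The slowest-germinating line is sown first (offset 0); every other line is
    sown ``max(t50) - t50`` hours later so all lines are expected to germinate
    at the same wall-clock moment.
    """
    if not t50_by_line:
        raise ValueError("no t50 values supplied")
    missing = [line for line, t in t50_by_line.items() if t is None or not np.isfinite(t)]
    if missing:
        raise ValueError(f"missing t50 for line(s): {', '.join(sorted(missing))}")
    slowest = max(t50_by_line.values())
    return {line: float(slowest - t) for line, t in t50_by_line.items()}


def seed_area_screen(
    table: pd.DataFrame,
    control_id: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Flag accessions whose seed area significantly exceeds the control line.

    Parameters
    ----------
    table : DataFrame
        Tidy seed-area table with columns ``accession_id`` and ``area``
        (mm^2, one row per measured seed/replicate).
    control_id : str
        Accession serving as the size reference.
    alpha : float
        Significance level of the two-sided Student's t-test (default 0.01).

    Returns
    -------
    DataFrame indexed by accession with columns ``mean``, ``n``, ``p``,
    ``larger_than_control`` and ``exclude``. An accession is flagged (and
    marked for exclusion from hybrid panels) only when the two-sided p-value
    is below ``alpha`` AND its mean area exceeds the control mean: a
    significantly *smaller* accession is not excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if control_id not in set(table["accession_id"]):
        raise ValueError(f"control accession {control_id!r} absent from table")
    areas = table.groupby("accession_id")["area"]
    if (table["area"] <= 0).any():
        raise ValueError("seed areas must be positive")
    control = areas.get_group(control_id).to_numpy()
    if control.size < 2:
        raise ValueError("control accession needs at least 2 replicates")

    rows = []
    for accession, values in areas:
        values = values.to_numpy()
        if accession == control_id:
            rows.append((accession, values.mean(), values.size, np.nan, False, False))
            continue
        if values.size < 2:
            warnings.warn(
                f"accession {accession!r} skipped: fewer than 2 replicates", stacklevel=2
            )
            continue
        res = students_t_test(values, control)
        larger = bool(res.p < alpha and values.mean() > control.mean())
        rows.append((accession, values.mean(), values.size, res.p, larger, larger))
    out = pd.DataFrame(
        rows, columns=["accession_id", "mean", "n", "p", "larger_than_control", "exclude"]
    )
    return out.set_index("accession_id")
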
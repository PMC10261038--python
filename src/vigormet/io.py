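"""Readers and writers for the pipeline's tidy-CSV interfaces.

One CSV dialect throughout: UTF-8, comma separator, header row, "." decimal,
missing values as empty fields. Every writer's output round-trips losslessly
through the matching reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from vigormet.germination import GerminationCourse
from vigormet.heterosis import ROLES

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_trait_table",
    "write_trait_table",
    "read_germination_courses",
    "write_germination_courses",
    "read_seed_areas",
    "write_seed_areas",
]

TRAIT_COLUMNS = ["combination_id", "line_id", "role", "replicate", "value"]


def read_trait_table(path) -> pd.DataFrame:
    """Validated replicate-level trait table.

    Requires all four roles (parent1, parent2, F1, F1rec) for every
    combination, positive values and >= 2 replicates per role.
    """
    table = pd.read_csv(path)
    missing_cols = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    bad_roles = set(table["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"{path}: unknown role(s) {sorted(bad_roles)}")
    incomplete = []
    for combo, sub in table.groupby("combination_id"):
        if set(sub["role"]) != set(ROLES):
            incomplete.append(str(combo))
        elif (sub.groupby("role").size() < 2).any():
            incomplete.append(str(combo))
    if incomplete:
        raise ValueError(
            f"{path}: combination(s) missing roles or replicates: {', '.join(sorted(incomplete))}"
        )
    if (table["value"] <= 0).any():
        raise ValueError(f"{path}: trait values must be positive")
    return table[TRAIT_COLUMNS]


def write_trait_table(table: pd.DataFrame, path) -> None:
    table[TRAIT_COLUMNS].to_csv(path, index=False)


def read_germination_courses(path) -> dict[str, GerminationCourse]:
    """Germination courses keyed by line, from a tidy long CSV."""
    df = pd.read_csv(path)
    required = {"line_id", "time_has", "fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: requires columns {sorted(required)}")
    courses = {}
    for line, sub in df.groupby("line_id"):
        sub = sub.sort_values("time_has")
        courses[str(line)] = GerminationCourse(
            line_id=str(line),
            times=sub["time_has"].to_numpy(),
            fractions=sub["fraction"].to_numpy(),
        )
    return courses


def write_germination_courses(courses: dict[str, GerminationCourse], path) -> None:
    pd.concat([c.to_frame() for c in courses.values()], ignore_index=True).to_csv(
        path, index=False
    )


def read_seed_areas(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"accession_id", "area"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: requires columns {sorted(required)}")
    return df


def write_seed_areas(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """End-to-end run settings; defaults follow the study's printed thresholds."""

    trait_table: str | None = None
    germination_courses: str | None = None
    seed_areas: str | None = None
    metabolite_matrix: str | None = None
    control_accession: str = "Col"
    fumarate_peak: str | None = None
    malate_peak: str | None = None
    seed_screen_alpha: float = 0.01
    heterosis_alpha: float = 0.05
    fdr: float = 0.05
    tukey_alpha: float = 0.05
    bph_threshold: float = 10.0
    impute: str = "halfmin"
    pca_scaling: str = "center"
    already_normalized: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_screen_alpha", "heterosis_alpha", "fdr", "tukey_alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.bph_threshold < 0:
            raise ValueError("bph_threshold must be >= 0")
        if self.impute not in ("halfmin", "offset"):
            raise ValueError("impute must be 'halfmin' or 'offset'")
        if self.pca_scaling not in ("center", "autoscale"):
            raise ValueError("pca_scaling must be 'center' or 'autoscale'")


def load_config(path) -> PipelineConfig:
    """YAML config with unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)
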
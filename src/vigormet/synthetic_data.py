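"""Synthetic trait, germination and metabolome data with known ground truth.

The generator emulates the measurement tables of a reciprocal-cross heterosis
study: replicate fresh-weight values for two parents and their two reciprocal
F1 hybrids, logistic cumulative germination curves, and GC-TOF-MS peak-area
matrices (by default 188 peaks, of which 103 carry annotations — including 10
stable-isotope internal standards — over 4 lines x 6 replicates = 24 samples).

Every generator is deterministic given (config, seed): the same call yields
byte-identical output. Ground truth (injected effects, the implied heterosis
class, the true fumarate/malate fold) is returned alongside the data, never
embedded in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from vigormet.germination import GerminationCourse
from vigormet.heterosis import compute_bpv
from vigormet.preprocess import MetaboliteMatrix

__all__ = [
    "CrossConfig",
    "MetabolomeConfig",
    "GroundTruth",
    "TCA_METABOLITES",
    "GERMINATION_SCHEDULE",
    "simulate_trait_table",
    "simulate_germination",
    "simulate_metabolome",
    "expected_class",
]

#: TCA cycle intermediates placed among the annotated peaks; "tca" in a
#: line-effect mapping targets this whole set.
TCA_METABOLITES = (
    "Citrate",
    "cis-Aconitate",
    "Isocitrate",
    "2-Oxoglutarate",
    "Succinate",
    "Fumarate",
    "Malate",
)

#: Cotyledon-opening observation schedule: every 12 h after sowing until 72
#: HAS, densified to every 4 h between 48 and 60 HAS.
GERMINATION_SCHEDULE = tuple(sorted(set(range(0, 73, 12)) | set(range(48, 61, 4))))


@dataclass(frozen=True)
class CrossConfig:
    """One reciprocal cross: parents, effect sizes and replicate noise."""

    parent1_id: str = "Col"
    parent2_id: str = "C24"
    parent_means: tuple[float, float] = (110.0, 90.0)  # mg fresh weight, 15 DAS
    heterosis_bph_pct: tuple[float, float] = (0.0, 0.0)  # (F1, F1rec), signed %
    cv: float = 0.05
    n_reps: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if any(m <= 0 for m in self.parent_means):
            raise ValueError("parent means must be positive")

    @property
    def combination_id(self) -> str:
        return f"{self.parent1_id}x{self.parent2_id}"

    @property
    def f1_id(self) -> str:
        return f"{self.parent1_id}x{self.parent2_id}"

    @property
    def f1rec_id(self) -> str:
        return f"{self.parent2_id}x{self.parent1_id}"


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) resampled until positive (truncation at 0)."""
    if sd == 0:
        return np.full(n, mean)
    values = rng.normal(mean, sd, size=n)
    while (values <= 0).any():
        bad = values <= 0
        values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return values


def simulate_trait_table(config: CrossConfig) -> pd.DataFrame:
    """Replicate-level trait table for the four lines of one cross.

    Hybrid population means are set to ``BPV * (1 + heterosis_bph_pct/100)``;
    replicates are Normal(mean, cv*mean) truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    bp = compute_bpv([config.parent_means[0]], [config.parent_means[1]])
    means = {
        "parent1": config.parent_means[0],
        "parent2": config.parent_means[1],
        "F1": bp.bpv * (1.0 + config.heterosis_bph_pct[0] / 100.0),
        "F1rec": bp.bpv * (1.0 + config.heterosis_bph_pct[1] / 100.0),
    }
    line_ids = {
        "parent1": config.parent1_id,
        "parent2": config.parent2_id,
        "F1": config.f1_id,
        "F1rec": config.f1rec_id,
    }
    records = []
    for role in ("parent1", "parent2", "F1", "F1rec"):
        values = _truncated_normal(rng, means[role], config.cv * means[role], config.n_reps)
        for rep, value in enumerate(values, start=1):
            records.append(
                {
                    "combination_id": config.combination_id,
                    "line_id": line_ids[role],
                    "role": role,
                    "replicate": rep,
                    "value": float(value),
                }
            )
    return pd.DataFrame.from_records(records)


def expected_class(config: CrossConfig, bph_threshold: float = 10.0) -> str:
    """Heterosis class implied by the configured effect sizes (the ground truth).

    Mirrors the classification decision tree with "significantly above/below"
    replaced by the sign of the injected BPH effect.
    """
    b1, b2 = config.heterosis_bph_pct
    above = (b1 > 0, b2 > 0)
    below = (b1 < 0, b2 < 0)
    if (above[0] and below[1]) or (above[1] and below[0]):
        return "unclassifiable"
    if all(above) and max(b1, b2) >= bph_threshold:
        return "high"
    if any(above) and min(b1, b2) >= 0 and max(b1, b2) < bph_threshold:
        return "weak"
    if not any(above):
        return "none"
    return "unclassifiable"


def simulate_germination(
    t50: float,
    slope: float,
    obs_times=GERMINATION_SCHEDULE,
    line_id: str = "line",
) -> GerminationCourse:
    """Noise-free logistic cumulative germination curve sampled at obs_times.

    ``fraction(t) = 1 / (1 + exp(-slope * (t - t50)))``; an infinite slope
    gives the step-function limit. If t50 lies outside the observation window
    the course is returned with a warning flag set.
    """
    times = np.asarray(obs_times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("obs_times must be nonempty and strictly increasing")
    if not slope > 0:
        raise ValueError("slope must be positive")
    if np.isinf(slope):
        fractions = np.where(times < t50, 0.0, np.where(times > t50, 1.0, 0.5))
    else:
        fractions = 1.0 / (1.0 + np.exp(-slope * (times - t50)))
    warning = None
    if not times[0] <= t50 <= times[-1]:
        warning = f"t50={t50} outside observation window [{times[0]}, {times[-1]}]"
    return GerminationCourse(line_id=line_id, times=times, fractions=fractions, warning=warning)


@dataclass(frozen=True)
class MetabolomeConfig:
    """Generator settings for one combination's peak-area matrix.

    ``line_effects`` maps a line id to multiplicative shifts keyed by peak
    annotation; the special key ``"tca"`` applies to every TCA intermediate
    (specific annotations override it). The per-sample technical scale factor
    (lognormal, sigma ``tech_sd_log``) multiplies all peaks of a sample,
    including the internal standards, and is what IS normalization removes.
    """

    n_peaks: int = 188
    n_known: int = 103
    n_is: int = 10
    n_reps: int = 6
    line_ids: tuple[str, str, str, str] = ("Col", "C24", "ColxC24", "C24xCol")
    line_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd_log2: float = 0.1
    tech_sd_log: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_is < self.n_peaks:
            raise ValueError("n_is must be smaller than n_peaks")
        if not self.n_known <= self.n_peaks:
            raise ValueError("n_known cannot exceed n_peaks")
        if self.n_is > self.n_known:
            raise ValueError("internal standards are annotated, so n_is <= n_known")
        if self.n_known - self.n_is < len(TCA_METABOLITES):
            raise ValueError("too few annotated peaks to host the TCA set")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.noise_sd_log2 < 0 or self.tech_sd_log < 0:
            raise ValueError("noise scales must be >= 0")
        for line, effects in self.line_effects.items():
            for key, factor in effects.items():
                if not factor > 0:
                    raise ValueError(
                        f"multiplicative effect for ({line!r}, {key!r}) must be positive"
                    )

    def with_seed(self, seed: int) -> "MetabolomeConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Injected effects and the statistics they imply.

    ``effects`` has one row per (line, peak) with a non-unit multiplicative
    shift; ``true_ratio_fold`` maps each line to its true fumarate/malate
    ratio fold over the mid-parent ratio.
    """

    effects: pd.DataFrame
    true_ratio_fold: dict[str, float]
    true_class: str | None = None

    def differential_peaks(self, line_id: str) -> pd.DataFrame:
        sub = self.effects[self.effects["line_id"] == line_id]
        return sub.assign(direction=np.where(sub["effect"] > 1, "up", "down"))


def _peak_annotations(config: MetabolomeConfig) -> pd.DataFrame:
    n_named = config.n_known - config.n_is
    annotations = [f"IS_{i + 1:02d}" for i in range(config.n_is)]
    annotations += list(TCA_METABOLITES)
    annotations += [f"Metabolite_{i + 1:03d}" for i in range(n_named - len(TCA_METABOLITES))]
    annotations += ["unknown"] * (config.n_peaks - config.n_known)
    peak_ids = [f"peak_{i + 1:03d}" for i in range(config.n_peaks)]
    is_flag = [True] * config.n_is + [False] * (config.n_peaks - config.n_is)
    return pd.DataFrame(
        {"annotation": annotations, "is_internal_standard": is_flag},
        index=pd.Index(peak_ids, name="peak_id"),
    )


def _effect_for(config: MetabolomeConfig, line: str, annotation: str) -> float:
    effects = config.line_effects.get(line, {})
    if annotation in effects:
        return float(effects[annotation])
    if annotation in TCA_METABOLITES and "tca" in effects:
        return float(effects["tca"])
    return 1.0


def simulate_metabolome(config: MetabolomeConfig) -> tuple[MetaboliteMatrix, GroundTruth]:
    """Peak-area matrix of n_peaks x (4 lines x n_reps) with ground truth.

    Each non-IS peak draws a baseline abundance; a line's samples multiply it
    by the configured effect and lognormal biological noise. Every sample —
    IS peaks included — is further multiplied by its technical scale factor.
    The technical log-factors are recentred to geometric mean 1 so that
    IS normalization reproduces the noise-free signal exactly.
    """
    rng = np.random.default_rng(config.seed)
    peaks = _peak_annotations(config)
    n_samples = 4 * config.n_reps
    columns = [
        f"{line}.{rep}" for line in config.line_ids for rep in range(1, config.n_reps + 1)
    ]

    base_log2 = rng.uniform(8.0, 20.0, size=config.n_peaks)
    base = np.power(2.0, base_log2)
    # IS compounds are spiked at a fixed known concentration
    base[: config.n_is] = np.power(2.0, rng.uniform(14.0, 16.0, size=config.n_is))

    log_tech = rng.normal(0.0, config.tech_sd_log, size=n_samples)
    log_tech -= log_tech.mean()  # geometric mean exactly 1
    tech = np.exp(log_tech)

    is_mask = peaks["is_internal_standard"].to_numpy()
    data = np.empty((config.n_peaks, n_samples))
    effect_rows = []
    for j, column in enumerate(columns):
        line = column.rpartition(".")[0]
        eff = np.array(
            [_effect_for(config, line, ann) for ann in peaks["annotation"]]
        )
        noise = np.power(2.0, rng.normal(0.0, config.noise_sd_log2, size=config.n_peaks))
        noise[is_mask] = 1.0  # IS spikes carry only the technical factor
        eff[is_mask] = 1.0
        data[:, j] = base * eff * noise * tech[j]
    for line in config.line_ids:
        for peak_id, ann in peaks["annotation"].items():
            if is_mask[peaks.index.get_loc(peak_id)]:
                continue
            eff = _effect_for(config, line, ann)
            if eff != 1.0:
                effect_rows.append(
                    {"line_id": line, "peak_id": peak_id, "annotation": ann, "effect": eff}
                )

    matrix = MetaboliteMatrix(
        peaks, pd.DataFrame(data, index=peaks.index, columns=columns), scale="linear"
    )

    p1, p2, f1, f1rec = config.line_ids
    true_ratio = {
        line: _effect_for(config, line, "Fumarate") / _effect_for(config, line, "Malate")
        for line in config.line_ids
    }
    mpv_ratio = (true_ratio[p1] + true_ratio[p2]) / 2.0
    truth = GroundTruth(
        effects=pd.DataFrame(
            effect_rows, columns=["line_id", "peak_id", "annotation", "effect"]
        ),
        true_ratio_fold={line: true_ratio[line] / mpv_ratio for line in config.line_ids},
    )
    return matrix, truth
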
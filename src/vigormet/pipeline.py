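"""End-to-end orchestration: generate, screen, classify, profile, summarise.

`run_pipeline` chains the stages in the order of the underlying experiment —
seed-area screen, germination synchronisation, heterosis classification,
metabolite preprocessing, differential calls, fumarate/malate ratios, PCA —
and writes each stage's output plus a manifest that is sufficient to rerun
the analysis identically.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vigormet import __version__
from vigormet.differential import differential_table, heatmap_table
from vigormet.germination import estimate_t50, seed_area_screen, sowing_offsets
from vigormet.heterosis import evaluate_combination, summarize_population
from vigormet.io import (
    PipelineConfig,
    read_germination_courses,
    read_seed_areas,
    read_trait_table,
    write_germination_courses,
    write_seed_areas,
    write_trait_table,
)
from vigormet.pca import group_separation_summary, run_pca
from vigormet.preprocess import MetaboliteMatrix, count_annotated, impute_and_log2, is_normalize
from vigormet.synthetic_data import (
    CrossConfig,
    MetabolomeConfig,
    simulate_germination,
    simulate_metabolome,
    simulate_trait_table,
)
from vigormet.tca import analyze_ratios

__all__ = ["generate_bundle", "run_pipeline", "reproduce_supplementary"]


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def generate_bundle(out_dir, seed: int = 0) -> dict[str, str]:
    """Write a complete synthetic input bundle for the pipeline.

    Produces a trait table with one combination per heterosis class,
    germination courses and seed areas for the parental panel, and a
    metabolite matrix for the high-heterosis combination with a TCA
    depression + fumarate/malate elevation signature in both hybrids.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    cross_specs = [
        ("Col", "C24", (32.9, 11.6)),  # high
        ("Col", "Ler-1", (8.9, 1.8)),  # weak
        ("Col", "Ws-0", (1.0, -1.0)),  # none (effects below detectability)
    ]
    tables = []
    for i, (p1, p2, bph) in enumerate(cross_specs):
        config = CrossConfig(
            parent1_id=p1,
            parent2_id=p2,
            parent_means=(110.0, 90.0),
            heterosis_bph_pct=bph,
            cv=0.05,
            n_reps=6,
            seed=rng_seed + i,
        )
        tables.append(simulate_trait_table(config))
    trait_table = pd.concat(tables, ignore_index=True)
    write_trait_table(trait_table, out / "trait_table.csv")

    lines = ["Col", "C24", "Ler-1", "Ws-0"]
    courses = {
        line: simulate_germination(t50=50.0 + 2.0 * i, slope=0.5, line_id=line)
        for i, line in enumerate(lines)
    }
    write_germination_courses(courses, out / "germination.csv")

    rng = np.random.default_rng(rng_seed)
    seed_rows = []
    for line in lines + ["Est"]:
        mean = 0.11 if line != "Est" else 0.15  # Est emulates a large-seeded accession
        areas = rng.normal(mean, 0.01, size=30).clip(min=1e-3)
        seed_rows.append(pd.DataFrame({"accession_id": line, "area": areas}))
    write_seed_areas(pd.concat(seed_rows, ignore_index=True), out / "seed_areas.csv")

    met_config = MetabolomeConfig(
        line_ids=("Col", "C24", "ColxC24", "C24xCol"),
        line_effects={
            "ColxC24": {"tca": 0.7, "Fumarate": 1.54, "Malate": 0.7},
            "C24xCol": {"tca": 0.7, "Fumarate": 1.33, "Malate": 0.7},
        },
        seed=rng_seed,
    )
    matrix, truth = simulate_metabolome(met_config)
    matrix.to_csv(out / "metabolite_matrix.csv")
    truth.effects.to_csv(out / "ground_truth_effects.csv", index=False)

    paths = {
        "trait_table": str(out / "trait_table.csv"),
        "germination_courses": str(out / "germination.csv"),
        "seed_areas": str(out / "seed_areas.csv"),
        "metabolite_matrix": str(out / "metabolite_matrix.csv"),
        "ground_truth": str(out / "ground_truth_effects.csv"),
    }
    _log("generate", f"wrote synthetic bundle to {out}")
    return paths


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage for which the config names an input; write a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}

    def run_stage(name: str, fn) -> None:
        try:
            files = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        outputs[name] = files

    if config.seed_areas:
        def seed_screen_stage() -> list[str]:
            table = read_seed_areas(config.seed_areas)
            screen = seed_area_screen(table, config.control_accession, config.seed_screen_alpha)
            screen.to_csv(out / "seed_screen.csv")
            _log("seed-screen", f"{int(screen['exclude'].sum())} accession(s) excluded")
            return ["seed_screen.csv"]

        run_stage("seed-screen", seed_screen_stage)

    if config.germination_courses:
        def sowing_stage() -> list[str]:
            courses = read_germination_courses(config.germination_courses)
            t50s = {line: estimate_t50(c) for line, c in courses.items()}
            germinated = {line: e.t50 for line, e in t50s.items() if e.status == "ok"}
            offsets = sowing_offsets(germinated)
            plan = pd.DataFrame(
                {
                    "line_id": list(t50s),
                    "t50_has": [t50s[line].t50 for line in t50s],
                    "status": [t50s[line].status for line in t50s],
                    "sowing_offset_h": [offsets.get(line) for line in t50s],
                }
            )
            plan.to_csv(out / "sowing_plan.csv", index=False)
            _log("sowing-plan", f"{len(germinated)} line(s) synchronised")
            return ["sowing_plan.csv"]

        run_stage("sowing-plan", sowing_stage)

    if config.trait_table:
        def classify_stage() -> list[str]:
            table = read_trait_table(config.trait_table)
            results = [
                evaluate_combination(
                    sub, alpha=config.heterosis_alpha, bph_threshold=config.bph_threshold
                )
                for _, sub in table.groupby("combination_id")
            ]
            pd.DataFrame([r.to_row() for r in results]).to_csv(
                out / "heterosis_results.csv", index=False
            )
            summarize_population(results).to_csv(out / "heterosis_summary.csv")
            _log("classify", f"{len(results)} combination(s) classified")
            return ["heterosis_results.csv", "heterosis_summary.csv"]

        run_stage("classify", classify_stage)

    if config.metabolite_matrix:
        state: dict = {}

        def preprocess_stage() -> list[str]:
            matrix = MetaboliteMatrix.from_csv(config.metabolite_matrix)
            lines = matrix.lines
            if len(lines) != 4:
                raise ValueError(f"expected 4 lines in matrix, got {lines}")
            files = []
            if not config.already_normalized:
                matrix, factors = is_normalize(matrix)
                factors.to_csv(out / "is_factors.csv")
                files.append("is_factors.csv")
            counts = count_annotated(matrix)
            log2_matrix = impute_and_log2(matrix, mode=config.impute)
            log2_matrix.to_csv(out / "matrix_log2.csv")
            files.append("matrix_log2.csv")
            state.update(matrix=matrix, log2=log2_matrix, lines=lines)
            _log("preprocess", f"{counts['n_known']} annotated of {counts['n_peaks']} peaks")
            return files

        run_stage("preprocess", preprocess_stage)
        parent1, parent2, hybrid1, hybrid2 = state["lines"]

        def diff_stage() -> list[str]:
            tables = {
                hybrid: differential_table(
                    state["log2"], hybrid, parent1, parent2, fdr=config.fdr
                )
                for hybrid in (hybrid1, hybrid2)
            }
            files = []
            for hybrid, table in tables.items():
                name = f"differential_{hybrid}.csv"
                table.to_csv(out / name)
                files.append(name)
            heatmap_table(tables).formatted().to_csv(out / "heatmap.csv")
            files.append("heatmap.csv")
            _log("diff", "differential tables written")
            return files

        run_stage("diff", diff_stage)

        def tca_stage() -> list[str]:
            matrix = state["matrix"]
            annotations = matrix.peaks["annotation"]
            fumarate = config.fumarate_peak
            malate = config.malate_peak
            if fumarate is None or malate is None:
                fum_ids = annotations.index[annotations == "Fumarate"]
                mal_ids = annotations.index[annotations == "Malate"]
                if len(fum_ids) != 1 or len(mal_ids) != 1:
                    _log("tca-ratio", "fumarate/malate peaks not identified; stage skipped")
                    return []
                fumarate, malate = fum_ids[0], mal_ids[0]
            ratios = analyze_ratios(
                matrix,
                fumarate,
                malate,
                parents=(parent1, parent2),
                hybrids=(hybrid1, hybrid2),
                alpha=config.tukey_alpha,
            )
            ratios.to_frame().to_csv(out / "tca_ratios.csv", index=False)
            _log("tca-ratio", f"folds vs MPV: {ratios.fold_vs_mpv}")
            return ["tca_ratios.csv"]

        run_stage("tca-ratio", tca_stage)

        def pca_stage() -> list[str]:
            pca = run_pca(state["log2"], scaling=config.pca_scaling)
            pca.scores.to_csv(out / "pca_scores.csv")
            pca.loadings.to_csv(out / "pca_loadings.csv")
            pd.DataFrame(
                {"component": pca.scores.columns, "explained_pct": pca.explained_pct}
            ).to_csv(out / "pca_explained.csv", index=False)
            groups = dict(zip(state["log2"].sample_names, state["log2"].samples["line_id"]))
            centroids, _ = group_separation_summary(pca, groups)
            centroids.to_csv(out / "pca_centroids.csv")
            _log("pca", f"PC1 {pca.explained_pct[0]:.2f}%")
            return ["pca_scores.csv", "pca_loadings.csv", "pca_explained.csv", "pca_centroids.csv"]

        run_stage("pca", pca_stage)

    manifest = {
        "vigormet_version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": list(outputs),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def reproduce_supplementary(
    matrix_csv,
    parents: tuple[str, str],
    hybrids: tuple[str, str],
    fumarate_peak: str,
    malate_peak: str,
    already_normalized: bool = True,
) -> dict:
    """Headline numbers from a published (supplementary) metabolite matrix.

    Computes the fumarate/malate fold vs MPV per hybrid under both MPV
    conventions, PC1/PC2 percent variance under both scaling conventions,
    and the annotated-peak counts. The matrix CSV must follow the package's
    tidy layout; pass ``already_normalized=False`` for raw areas.
    """
    matrix = MetaboliteMatrix.from_csv(matrix_csv, normalized=already_normalized)
    if not already_normalized:
        matrix, _ = is_normalize(matrix)
    counts = count_annotated(matrix)
    ratios = analyze_ratios(
        matrix, fumarate_peak, malate_peak, parents=parents, hybrids=hybrids
    )
    log2_matrix = impute_and_log2(matrix)
    out = {
        "n_peaks": counts["n_peaks"],
        "n_known": counts["n_known"],
        "fold_vs_mpv": ratios.fold_vs_mpv,
        "fold_vs_mpv_area_convention": ratios.fold_vs_mpv_area_convention,
    }
    for scaling in ("center", "autoscale"):
        pca = run_pca(log2_matrix, scaling=scaling)
        out[f"pc1_pct_{scaling}"] = float(pca.explained_pct[0])
        out[f"pc2_pct_{scaling}"] = float(pca.explained_pct[1])
    return out
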
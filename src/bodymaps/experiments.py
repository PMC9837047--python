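"""Planted-effect recovery experiments over many synthetic cohorts.

These drivers run the full pipeline repeatedly on freshly generated cohorts
at the study's conditions (n = 228 subjects, 10 emotions, 120 x 44
silhouette) and collect the statistics whose planted values are known, so
recovery can be scored. Iteration-heavy analysis settings (permutation
counts, Hadi repetitions, CV splits) are scaled to desk size here — see
docs/methods.md for the exact sizes; the generator conditions themselves are
never scaled.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .pipeline import AnalysisConfig, StudyConfig, run_pipeline
from .simulate import (
    COMPONENTS,
    FACTORS,
    GeneratorConfig,
    generate_questionnaires,
    sample_cohort_latents,
)
from .decomposition import signflip_retention

__all__ = [
    "recovery_analysis_config",
    "run_recovery_cohorts",
    "personality_retention_counts",
    "idiosyncrasy_sweep",
]


def recovery_analysis_config() -> AnalysisConfig:
    """Desk-scale analysis settings for multi-cohort recovery runs.

    Map rank is fixed at the four interpretable components (the association
    stage's component count); personality retention keeps its permutation
    test at a reduced permutation count; classifier CV splits and loading
    bootstraps are skipped — none of those quantities are scored by the
    recovery experiments.
    """
    return AnalysisConfig(
        n_perm=200,
        n_boot=0,
        n_splits=0,
        hadi_reps=10,
        map_n_components=4,
        compute_bootstrap=False,
    )


def _cohort_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32) % (
        2**31
    )


def run_recovery_cohorts(
    n_cohorts: int = 100,
    seed: int = 0,
    generator: GeneratorConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full pipeline on ``n_cohorts`` fresh cohorts; one row of recovered
    statistics per cohort.

    Columns: every personality x map-component Spearman (``factor~component``),
    the salience correlations (``component~body/mind``), and the granularity
    correlations (``factor~confidence/differentiation/representativeness``).
    """
    generator = generator or GeneratorConfig()
    analysis = analysis or recovery_analysis_config()
    rows = []
    for cohort_seed in _cohort_seeds(seed, n_cohorts):
        cfg = StudyConfig(generator=generator, analysis=analysis, seed=int(cohort_seed))
        res = run_pipeline(cfg)
        row: dict[str, float] = {"seed": int(cohort_seed)}
        for rec in res["association_table"].to_dict("records"):
            row[f"{rec['var_a']}~{rec['var_b']}"] = rec["rho"]
        for rec in res["salience_table"].to_dict("records"):
            row[f"{rec['var_a']}~{rec['var_b']}"] = rec["rho"]
        for rec in res["summary"]["granularity_association"]:
            row[f"{rec['var_a']}~{rec['var_b']}"] = rec["rho"]
        row["accuracy"] = res["summary"]["accuracy"]
        row["n_retained_personality"] = res["summary"][
            "personality_components_retained"
        ]
        rows.append(row)
    return pd.DataFrame(rows)


def personality_retention_counts(
    n_seeds: int = 50,
    seed: int = 0,
    n_subjects: int = 228,
    n_perm: int = 1000,
    generator: GeneratorConfig | None = None,
) -> list[int]:
    """Retained-component counts of the personality PCA across seeds.

    Generates the questionnaire battery from the default five-factor model at
    the study sample size, runs the sign-flip permutation test on the
    correlation-matrix PCA of the scale scores, and returns the retained
    count per seed (the modal count is the quantity of interest).
    """
    generator = generator or GeneratorConfig(n_subjects=n_subjects)
    counts = []
    for s in _cohort_seeds(seed, n_seeds):
        latents = sample_cohort_latents(generator, np.random.default_rng(int(s)))
        q = generate_questionnaires(
            latents,
            scales=generator.scales,
            n_items_per_scale=generator.n_items_per_scale,
            n_reversed_items=generator.n_reversed_items,
            noise_sd=generator.item_noise_sd,
            slope=generator.item_slope,
            likert_levels=generator.likert_levels,
            rng=np.random.default_rng(int(s) + 1),
        )
        ret = signflip_retention(
            q.scale_scores.to_numpy(),
            n_perm=n_perm,
            percentile=95.0,
            seed=np.random.default_rng(int(s) + 2),
            center=True,
            scale=True,
        )
        counts.append(ret.n_retained)
    return counts


def idiosyncrasy_sweep(
    idio_grid: tuple[float, ...] = (0.0, 0.6, 1.2),
    n_subjects: int = 100,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean representativeness and classifier confidence across an
    idiosyncrasy grid (monotone-contract Monte Carlo).

    Each grid point sets the generator's maximum idiosyncrasy weight and runs
    the rendered pipeline end to end; both metrics should decrease
    monotonically in the idiosyncrasy level.
    """
    rows = []
    analysis = recovery_analysis_config()
    analysis = dataclasses.replace(analysis, screening_enabled=False)
    for lam in idio_grid:
        reps = []
        confs = []
        for r in range(n_reps):
            gen = GeneratorConfig(n_subjects=n_subjects, idio_max=lam)
            cfg = StudyConfig(
                generator=gen, analysis=analysis, seed=int(seed + 1000 * r + 7)
            )
            res = run_pipeline(cfg)
            reps.append(res["granularity"]["representativeness"].mean())
            confs.append(res["granularity"]["confidence"].mean())
        rows.append(
            {
                "idio_max": lam,
                "mean_representativeness": float(np.mean(reps)),
                "mean_confidence": float(np.mean(confs)),
            }
        )
    return pd.DataFrame(rows)
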
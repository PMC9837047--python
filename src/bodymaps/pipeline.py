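"""Study configuration and the end-to-end analysis pipeline.

``run_pipeline`` chains simulate -> screen -> decompose -> associate ->
granularity on one synthetic (or loaded) study and returns a JSON-ready
summary; all randomness flows from a single master seed through named
per-stage substreams, so identical (config, seed) yield identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import granularity as gran
from ._utils import substream
from .decomposition import (
    ComponentModel,
    fit_pca,
    rotate_model,
    signflip_retention,
)
from .mask import BodyMask
from .screening import ScreeningReport, completeness_screen, repeated_subset_screen
from .simulate import (
    COMPONENTS,
    EMOTIONS,
    FACTORS,
    GeneratorConfig,
    StudyDataset,
    generate_study,
)

__all__ = ["AnalysisConfig", "StudyConfig", "run_pipeline", "name_map_components"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants; defaults are the full-scale study settings
    (1000 permutations / bootstraps / CV splits, 95th-percentile retention,
    5% outlier alpha, 10% removal threshold, 5% extreme groups)."""

    n_perm: int = 1000  # sign-flip permutations for retention
    n_boot: int = 1000  # bootstrap resamplings for loading z-scores
    n_splits: int = 1000  # cross-validation splits for the classifier
    percentile: float = 95.0  # retention envelope percentile
    alpha: float = 0.05  # Hadi per-observation significance level
    removal_threshold: float = 0.10  # Hadi flag-rate removal threshold
    hadi_reps: int = 1000  # random item subsets for the Hadi screen
    subset_frac: float = 0.5  # item fraction per Hadi repetition
    min_empty_maps: int = 3  # completeness rule
    pct_extreme: float = 5.0  # extreme-group percentage
    n_components_for_association: int = 4
    map_n_components: int | None = None  # fixed map rank; None = permutation test
    map_channels: str = "signed"  # "signed" or "split" (activation|deactivation)
    screening_enabled: bool = True
    compute_bootstrap: bool = False
    chance: float = 0.10


@dataclass(frozen=True)
class StudyConfig:
    """Generator conditions + analysis constants + master seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def config_hash(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(
            {
                "generator": {
                    k: _default(v) if not isinstance(v, (int, float, str, bool)) else v
                    for k, v in asdict(self.generator).items()
                    if k != "spearman_targets"
                },
                "targets": sorted(
                    (list(k), v) for k, v in self.generator.spearman_targets.items()
                ),
                "analysis": asdict(self.analysis),
                "seed": self.seed,
            },
            sort_keys=True,
            default=_default,
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# component naming


_REGION_GROUPS = {
    "head": ("head", "upper_chest"),
    "stomach": ("stomach",),
    "legs": ("legs", "feet"),
    "heart": ("heart_area",),
    "arms": ("arms", "hands"),
    "torso": ("other_torso",),
}


def name_map_components(
    model: ComponentModel,
    mask: BodyMask,
    grand_mean: np.ndarray,
    signed_loadings: np.ndarray | None = None,
) -> tuple[list[str], ComponentModel]:
    """Label rotated map components by dominant body region and orient them.

    Each component is named after the region group holding most of its
    squared loading mass. Orientation is data-driven: the component is
    flipped, if needed, so that its loading direction in the dominant region
    agrees with the sign the cohort actually paints there (the grand-mean
    map); a component pointing at a region the cohort paints negatively is
    named a deactivation, otherwise an activation. Duplicate names get a
    numeric suffix. For two-channel (split activation/deactivation) models,
    pass ``signed_loadings`` (activation minus deactivation channel, one row
    per pixel) and the signed grand mean; naming runs on the signed view
    while flips apply to the full model.
    """
    L = model.loadings.copy()
    S = model.scores.copy()
    Ls = L if signed_loadings is None else signed_loadings.copy()
    names: list[str] = []
    seen: dict[str, int] = {}
    for k in range(L.shape[1]):
        masses = {
            g: float(
                sum(np.sum(Ls[mask.region_vector(r), k] ** 2) for r in regions)
            )
            for g, regions in _REGION_GROUPS.items()
        }
        group = max(masses, key=masses.get)
        sel = np.zeros(mask.n_pixels, dtype=bool)
        for r in _REGION_GROUPS[group]:
            sel |= mask.region_vector(r)
        painted = float(np.sum(grand_mean[sel]))
        loading_dir = float(np.sum(Ls[sel, k]))
        if painted * loading_dir < 0:
            L[:, k] *= -1
            S[:, k] *= -1
            loading_dir *= -1
        kind = "deactivation" if loading_dir < 0 else "activation"
        base = f"{group}_{kind}"
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
    oriented = ComponentModel(
        loadings=L,
        eigenvalues=model.eigenvalues,
        rotation=model.rotation,
        scores=S,
        center=model.center,
        scale=model.scale,
        variable_ids=model.variable_ids,
        observation_keys=model.observation_keys,
    )
    return names, oriented


def name_personality_components(
    model: ComponentModel, loading_spec: pd.DataFrame
) -> tuple[list[str], ComponentModel]:
    """Match rotated personality components to the configured factor markers.

    Components are assigned factor names by greedy maximal |Tucker
    congruence| against the marker loading pattern and sign-oriented so the
    congruence is positive (so e.g. the antisocial component scores increase
    with psychopathy/social dominance and decrease with empathy).
    """
    from .decomposition import tucker_congruence

    Lambda = loading_spec.to_numpy()  # scales x factors
    C = tucker_congruence(model.loadings, Lambda)  # K x F
    K = model.loadings.shape[1]
    names = [""] * K
    L = model.loadings.copy()
    S = model.scores.copy()
    free_factors = list(range(Lambda.shape[1]))
    order = np.argsort(-np.max(np.abs(C), axis=1), kind="stable")
    for k in order:
        if not free_factors:
            names[k] = f"component_{k + 1}"
            continue
        f = max(free_factors, key=lambda f: abs(C[k, f]))
        if C[k, f] < 0:
            L[:, k] *= -1
            S[:, k] *= -1
        names[k] = loading_spec.columns[f]
        free_factors.remove(f)
    oriented = ComponentModel(
        loadings=L,
        eigenvalues=model.eigenvalues,
        rotation=model.rotation,
        scores=S,
        center=model.center,
        scale=model.scale,
        variable_ids=model.variable_ids,
        observation_keys=model.observation_keys,
    )
    return names, oriented


# ---------------------------------------------------------------------------
# pipeline


def _screen(ds: StudyDataset, cfg: AnalysisConfig, seed: int) -> ScreeningReport:
    comp = completeness_screen(ds.maps, ds.subject_ids, min_empty=cfg.min_empty_maps)
    hadi = repeated_subset_screen(
        ds.questionnaire.item_responses,
        n_reps=cfg.hadi_reps,
        subset_frac=cfg.subset_frac,
        alpha=cfg.alpha,
        removal_threshold=cfg.removal_threshold,
        seed=substream(seed, "screening"),
    )
    return ScreeningReport.union(comp, hadi)


def run_pipeline(config: StudyConfig, dataset: StudyDataset | None = None) -> dict:
    """Execute every stage on one study and return the result bundle.

    Returns a dict with the screening report, fitted models, score tables,
    association and salience tables, granularity metrics and a JSON-ready
    ``summary``.
    """
    seed = config.seed
    acfg = config.analysis
    ds = dataset if dataset is not None else generate_study(config.generator, seed)
    n0 = len(ds.subject_ids)

    # --- screening ----------------------------------------------------------
    if acfg.screening_enabled:
        report = _screen(ds, acfg, seed)
    else:
        report = ScreeningReport(removed=pd.DataFrame(columns=["subject_id", "reason"]))
    keep = [i for i, s in enumerate(ds.subject_ids) if s not in report.removed_ids]
    subjects = [ds.subject_ids[i] for i in keep]
    maps = ds.maps[keep]
    n = len(subjects)
    log.info("screening: %d of %d subjects retained", n, n0)

    # --- map decomposition --------------------------------------------------
    X_signed = maps.reshape(n * len(EMOTIONS), -1)
    if acfg.map_channels == "split":
        # activation and deactivation as separate nonnegative channels
        X_maps = np.concatenate(
            [np.clip(X_signed, 0, None), np.clip(-X_signed, 0, None)], axis=1
        )
    elif acfg.map_channels == "signed":
        X_maps = X_signed
    else:
        raise ValueError(f"unknown map_channels mode: {acfg.map_channels!r}")
    obs_keys = [(s, e) for s in subjects for e in EMOTIONS]
    if acfg.map_n_components is not None:
        k_maps = acfg.map_n_components
        map_retention = None
    else:
        map_retention = signflip_retention(
            X_maps,
            n_perm=acfg.n_perm,
            percentile=acfg.percentile,
            seed=substream(seed, "map-retention"),
        )
        k_maps = max(map_retention.n_retained, 1)
    map_model = rotate_model(
        fit_pca(X_maps, center=True, scale=False, n_components=k_maps,
                observation_keys=obs_keys)
    )
    if acfg.map_channels == "split":
        p = ds.mask.n_pixels
        signed_loadings = map_model.loadings[:p] - map_model.loadings[p:]
    else:
        signed_loadings = None
    map_names, map_model = name_map_components(
        map_model, ds.mask, X_signed.mean(axis=0), signed_loadings=signed_loadings
    )
    map_scores = pd.DataFrame(
        map_model.scores,
        index=pd.MultiIndex.from_tuples(obs_keys, names=["subject", "emotion"]),
        columns=map_names,
    )

    # --- personality decomposition -----------------------------------------
    scales = ds.questionnaire.scale_scores.loc[subjects]
    pers_retention = signflip_retention(
        scales.to_numpy(),
        n_perm=acfg.n_perm,
        percentile=acfg.percentile,
        seed=substream(seed, "personality-retention"),
        center=True,
        scale=True,
    )
    k_pers = max(pers_retention.n_retained, 1)
    pers_model = rotate_model(
        fit_pca(
            scales.to_numpy(),
            center=True,
            scale=True,
            n_components=k_pers,
            variable_ids=list(scales.columns),
            observation_keys=subjects,
        )
    )
    pers_names, pers_model = name_personality_components(
        pers_model, ds.questionnaire.scale_factor_loadings
    )
    pers_scores = pd.DataFrame(
        pers_model.scores, index=pd.Index(subjects, name="subject"), columns=pers_names
    )

    # --- association --------------------------------------------------------
    n_assoc = min(acfg.n_components_for_association, map_scores.shape[1])
    avg_map_scores = assoc.emotion_average_scores(map_scores.iloc[:, :n_assoc])
    table = assoc.spearman_fdr(pers_scores, avg_map_scores, fdr=True)
    avg_ratings = assoc.emotion_average_scores(ds.ratings.loc[subjects])
    salience = assoc.salience_correlations(avg_map_scores, avg_ratings)

    # --- granularity --------------------------------------------------------
    labels = map_scores.index.get_level_values("emotion").to_numpy()
    subj_arr = map_scores.index.get_level_values("subject").to_numpy()
    model = gran.fit_lda(map_scores.to_numpy(), labels)
    metrics = gran.granularity_metrics(map_scores, model=model).table
    significance = gran.classifier_significance(
        map_scores.to_numpy(),
        labels,
        subj_arr,
        n_splits=acfg.n_splits,
        chance=acfg.chance,
        seed=substream(seed, "cv-splits"),
    )
    gran_assoc = assoc.spearman_fdr(pers_scores, metrics, fdr=True)
    mediation = None
    if "antisocial" in pers_scores.columns:
        mediation = gran.sobel_mediation(
            pers_scores["antisocial"].to_numpy(),
            metrics["representativeness"].to_numpy(),
            metrics["differentiation"].to_numpy(),
        )

    summary = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_subjects_input": n0,
        "n_subjects_retained": n,
        "n_removed": int(len(report.removed)),
        "map_components_retained": (
            int(map_retention.n_retained) if map_retention else k_maps
        ),
        "personality_components_retained": int(pers_retention.n_retained),
        "map_component_names": map_names,
        "personality_component_names": pers_names,
        "association_table": table.to_dict("records"),
        "salience_table": salience.to_dict("records"),
        "accuracy": significance["accuracy"],
        "chi2": significance["chi2"],
        "p_param": significance["p_param"],
        "p_cv": significance["p_cv"],
        "granularity_association": gran_assoc.to_dict("records"),
        "mediation": mediation,
    }
    return {
        "dataset": ds,
        "screening": report,
        "map_model": map_model,
        "map_retention": map_retention,
        "map_scores": map_scores,
        "personality_model": pers_model,
        "personality_retention": pers_retention,
        "personality_scores": pers_scores,
        "association_table": table,
        "salience_table": salience,
        "granularity": metrics,
        "significance": significance,
        "mediation": mediation,
        "summary": summary,
    }
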
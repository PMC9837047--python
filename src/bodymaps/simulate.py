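"""Synthetic bodily-sensation-map cohorts with planted individual differences.

Generates complete synthetic studies — signed sensation maps painted on a body
silhouette for 10 emotions, an item-level personality battery organized around
five latent factors, and per-emotion experience ratings — whose latent
correlation structure is planted through a Gaussian copula. Every downstream
stage (screening, decomposition, association, granularity) can therefore be
exercised and scored against known ground truth.

The generative model of one subject's map for one emotion is

    map(s, e) = clip( sum_k score(s, e, k) * template_k
                      + lambda_s * idiopattern_s + eps, -1, +1 )

where the four spatial templates are unit-norm signed rasters (head/upper
chest activation, stomach activation, legs deactivation, heart activation),
``score(s, e, k)`` combines an emotion profile mean, a subject propensity
drawn from the copula, and an idiosyncratic emotion-profile perturbation
scaled by the subject's idiosyncrasy weight lambda_s, ``idiopattern_s`` is a
subject-specific smooth unit-norm raster, and eps is iid pixel noise.

Activation and deactivation are combined into one signed channel per map
(positive = activation, negative = deactivation), giving one variable per
silhouette pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm, spearmanr

from .mask import BodyMask, build_manikin_mask

__all__ = [
    "EMOTIONS",
    "COMPONENTS",
    "FACTORS",
    "EMOTION_PROFILE",
    "DEFAULT_SCALES",
    "RATING_QUESTIONS",
    "TemplateSet",
    "LatentState",
    "QuestionnaireData",
    "StudyDataset",
    "GeneratorConfig",
    "default_spearman_targets",
    "spearman_to_pearson",
    "build_copula_correlation",
    "build_component_templates",
    "sample_cohort_latents",
    "render_subject_maps",
    "generate_questionnaires",
    "generate_ratings",
    "inject_noncompliance",
    "generate_study",
    "calibrate_idiosyncrasy_link",
]

EMOTIONS = (
    "anger",
    "fear",
    "sadness",
    "happiness",
    "disgust",
    "surprise",
    "pride",
    "shame",
    "contempt",
    "envy",
)

#: Spatial component names; the legs component is a deactivation pattern
#: (non-positive template weights), the rest are activation patterns.
COMPONENTS = (
    "head_activation",
    "stomach_activation",
    "legs_deactivation",
    "heart_activation",
)

FACTORS = (
    "negative_affect",
    "antisocial",
    "positive_affect",
    "impulsivity",
    "interoception",
)

RATING_QUESTIONS = ("body", "mind", "pleasantness", "control", "frequency")

#: Mean component score per emotion (rows = EMOTIONS, cols = COMPONENTS).
#: Qualitative pattern: head activation present in most emotions and strongest
#: in anger/happiness/pride; stomach strongest in disgust and raised in the
#: distress emotions; legs deactivation in sadness/shame/fear/disgust; heart
#: in the high-arousal positive emotions and surprise.
EMOTION_PROFILE = np.array(
    [
        # head  stomach legs_de heart
        [1.00, 0.30, 0.10, 0.40],  # anger
        [0.80, 0.50, 0.80, 0.50],  # fear
        [0.50, 0.40, 1.00, 0.15],  # sadness
        [1.00, 0.20, 0.10, 0.90],  # happiness
        [0.60, 1.00, 0.60, 0.15],  # disgust
        [0.80, 0.30, 0.10, 0.70],  # surprise
        [1.00, 0.20, 0.10, 0.80],  # pride
        [0.70, 0.40, 0.80, 0.15],  # shame
        [0.60, 0.30, 0.20, 0.20],  # contempt
        [0.60, 0.30, 0.30, 0.30],  # envy
    ]
)

#: Default personality battery: (scale name, factor, signed loading).
#: Signs follow the component interpretation of the five-factor solution:
#: e.g. psychopathy and social dominance load positively and empathy
#: negatively on the antisocial-attitudes factor.
DEFAULT_SCALES = (
    ("panas_negative", "negative_affect", 0.92),
    ("stai_anxiety", "negative_affect", 0.92),
    ("lotr_optimism", "negative_affect", -0.92),
    ("pwb_environmental_mastery", "negative_affect", -0.92),
    ("pwb_self_acceptance", "negative_affect", -0.92),
    ("lsrp_primary_psychopathy", "antisocial", 0.92),
    ("sdo_social_dominance", "antisocial", 0.92),
    ("iri_empathic_concern", "antisocial", -0.92),
    ("staxi_anger_expression", "antisocial", 0.92),
    ("panas_positive", "positive_affect", 0.92),
    ("panas_joviality", "positive_affect", 0.92),
    ("stpi_depression", "positive_affect", -0.92),
    ("bis_impulsivity", "impulsivity", 0.92),
    ("lsrp_secondary_psychopathy", "impulsivity", 0.92),
    ("bfi_conscientiousness", "impulsivity", -0.92),
    ("panas_attentiveness", "impulsivity", -0.92),
    ("maia_interoception", "interoception", 0.92),
    ("panas_emotional_awareness", "interoception", 0.92),
    ("tas_difficulty_describing", "interoception", -0.92),
    ("tas_difficulty_identifying", "interoception", -0.92),
)

#: Mean shifts of each rating question per emotion (rows = EMOTIONS,
#: cols = RATING_QUESTIONS). Pleasantness high for positive emotions,
#: control lowest for fear/anger, frequency highest for happiness.
RATING_OFFSETS = np.array(
    [
        # body  mind  pleas ctrl  freq
        [0.6, 0.4, -0.8, -0.6, 0.0],  # anger
        [0.7, 0.5, -0.9, -0.8, -0.2],  # fear
        [0.3, 0.7, -0.9, -0.4, 0.1],  # sadness
        [0.6, 0.6, 1.0, 0.5, 0.8],  # happiness
        [0.7, 0.2, -0.9, -0.3, -0.3],  # disgust
        [0.5, 0.5, 0.2, -0.4, 0.0],  # surprise
        [0.5, 0.7, 0.9, 0.5, 0.4],  # pride
        [0.4, 0.7, -0.8, -0.4, -0.1],  # shame
        [0.2, 0.5, -0.4, 0.2, -0.2],  # contempt
        [0.3, 0.6, -0.6, -0.1, -0.2],  # envy
    ]
)

# Copula variables: 5 personality factors, 4 map-component propensities,
# the idiosyncrasy driver, and 5 rating latents.
_COPULA_VARS = FACTORS + COMPONENTS + ("idiosyncrasy",) + RATING_QUESTIONS

# Idiosyncrasy-driver link strengths produced by the shipped pre-run
# calibration (calibrate_idiosyncrasy_link) so that the pipeline-measured
# representativeness ~ factor Spearman hits the planted targets
# (-0.18 antisocial, -0.17 impulsivity).
RHO_IDIO_ANTISOCIAL = 0.484
RHO_IDIO_IMPULSIVITY = 0.388


def default_spearman_targets() -> dict[tuple[str, str], float]:
    """Planted Spearman correlations among copula variables.

    The three personality-map cells are the bold entries of the component
    correlation table; the rating links are the salience validation
    correlations; the idiosyncrasy-driver links are set by the calibration
    utility. All other pairs are zero.
    """
    return {
        ("antisocial", "stomach_activation"): -0.207,
        ("antisocial", "heart_activation"): -0.194,
        ("impulsivity", "head_activation"): -0.172,
        ("head_activation", "mind"): 0.23,
        ("heart_activation", "body"): 0.17,
        ("legs_deactivation", "body"): -0.16,
        ("idiosyncrasy", "antisocial"): RHO_IDIO_ANTISOCIAL,
        ("idiosyncrasy", "impulsivity"): RHO_IDIO_IMPULSIVITY,
    }


@dataclass(frozen=True)
class TemplateSet:
    """Unit-norm signed spatial templates on a shared mask (K x P)."""

    mask: BodyMask
    names: tuple[str, ...]
    values: np.ndarray  # K x P, vectorized over inside pixels

    def __post_init__(self):
        norms = np.linalg.norm(self.values, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("templates must be unit Euclidean norm")

    def cosine_matrix(self) -> np.ndarray:
        return self.values @ self.values.T


@dataclass
class LatentState:
    """Ground-truth latent variables of one synthetic cohort."""

    subject_ids: list[str]
    personality_factors: pd.DataFrame  # subject x 5
    map_propensities: pd.DataFrame  # subject x K (copula draws)
    map_scores: np.ndarray  # subject x emotion x K composed scores
    idiosyncrasy_weight: np.ndarray  # subject, >= 0
    rating_latents: pd.DataFrame  # subject x 5 questions
    copula_spec: dict[tuple[str, str], float]


@dataclass
class QuestionnaireData:
    """Item-level Likert battery plus keyed scale scores."""

    item_responses: pd.DataFrame  # subject x item (integer Likert)
    scale_scores: pd.DataFrame  # subject x scale (keyed sums)
    scale_factor_loadings: pd.DataFrame  # scale x 5 signed loadings
    true_scale_scores: pd.DataFrame  # subject x scale, pre-discretization
    item_keys: pd.Series  # +1 / -1 per item


@dataclass
class StudyDataset:
    """One complete synthetic study."""

    mask: BodyMask
    templates: TemplateSet
    subject_ids: list[str]
    maps: np.ndarray  # S x E x P signed values in [-1, 1]
    questionnaire: QuestionnaireData
    ratings: pd.DataFrame  # (subject, emotion) x question
    latents: LatentState
    noncompliance_flags: pd.DataFrame  # subject_id, kind


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort generator.

    Defaults are the study's conditions: 228 retained subjects, 10 emotions,
    a 120 x 44 silhouette (~1.7k inside pixels), high communalities so the
    pipeline-recovered scores track the latents closely, and the planted
    Spearman targets of :func:`default_spearman_targets`.
    """

    n_subjects: int = 228
    mask_height: int = 120
    mask_width: int = 44
    sigma_propensity: float = 0.5  # between-subject component-score SD
    sigma_within: float = 0.15  # within-subject emotion-score noise SD
    pixel_noise_sd: float = 0.02
    idio_max: float = 1.2  # lambda_s = idio_max * Phi(z_driver)
    idio_raster_scale: float = 0.25  # amplitude of the smooth idiopattern term
    idio_smooth_sigma: float = 4.0
    n_items_per_scale: int = 8
    n_reversed_items: int = 2
    item_noise_sd: float = 0.4
    item_slope: float = 0.9
    rating_noise_sd: float = 0.3
    rating_slope: float = 0.8
    likert_levels: int = 5
    frac_random_responders: float = 0.0
    frac_empty_map_subjects: float = 0.0
    spearman_targets: dict = field(default_factory=default_spearman_targets)
    scales: tuple = DEFAULT_SCALES


# ---------------------------------------------------------------------------
# copula


def spearman_to_pearson(rho_s: float | np.ndarray) -> float | np.ndarray:
    """Pearson correlation of a bivariate normal with given Spearman rho.

    Exact for bivariate normal ranks: r = 2 sin(pi rho_s / 6).
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def build_copula_correlation(
    targets: dict[tuple[str, str], float],
) -> tuple[np.ndarray, list[str]]:
    """Latent-normal correlation matrix realizing the Spearman targets.

    Raises ``ValueError`` naming the planted pairs if the converted matrix is
    not positive semidefinite.
    """
    names = list(_COPULA_VARS)
    idx = {n: i for i, n in enumerate(names)}
    R = np.eye(len(names))
    for (a, b), rho in targets.items():
        if a not in idx or b not in idx:
            raise KeyError(f"unknown copula variable in target pair ({a}, {b})")
        r = float(spearman_to_pearson(rho))
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-10:
        pairs = ", ".join(f"({a}, {b})={rho:+.3f}" for (a, b), rho in targets.items())
        raise ValueError(
            f"target Spearman matrix is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3e}); planted pairs: {pairs}"
        )
    return R, names


# ---------------------------------------------------------------------------
# templates


def _smooth_template(mask: BodyMask, raw: np.ndarray, sigma: float = 1.2) -> np.ndarray:
    sm = gaussian_filter(raw, sigma=sigma, mode="constant")
    vec = mask.vectorize(sm)
    return vec / np.linalg.norm(vec)


def build_component_templates(mask: BodyMask) -> TemplateSet:
    """Four unit-norm spatial templates matching the rotated map components.

    Head/upper-chest activation, stomach activation, legs deactivation
    (entirely non-positive), and heart activation. At least 80% of each
    template's squared mass lies inside its defining region(s), and pairwise
    |cosine| between templates is below 0.3.
    """
    raws = {
        "head_activation": 1.0 * mask.region("head") + 0.6 * mask.region("upper_chest"),
        "stomach_activation": 1.0 * mask.region("stomach"),
        "legs_deactivation": -1.0 * mask.region("legs") - 0.7 * mask.region("feet"),
        "heart_activation": 1.0 * mask.region("heart_area"),
    }
    values = np.stack(
        [_smooth_template(mask, raws[name].astype(float)) for name in COMPONENTS]
    )
    # smoothing of a one-signed raster preserves the sign everywhere
    assert (values[COMPONENTS.index("legs_deactivation")] <= 0).all()
    ts = TemplateSet(mask=mask, names=COMPONENTS, values=values)
    gram = np.abs(ts.cosine_matrix() - np.eye(len(COMPONENTS)))
    if gram.max() >= 0.3:
        raise ValueError("templates are insufficiently distinct (|cos| >= 0.3)")
    return ts


# ---------------------------------------------------------------------------
# latents


def sample_cohort_latents(
    config: GeneratorConfig, seed: int | np.random.Generator
) -> LatentState:
    """Draw one cohort's latent state from the Gaussian copula.

    Personality factors, map-component propensities, the idiosyncrasy driver
    and the rating latents are jointly normal with pairwise correlations
    converted from the planted Spearman targets; the composed per-emotion map
    scores add the emotion profile means, within-subject noise, and the
    idiosyncratic emotion-profile perturbation (centered across emotions so it
    leaves emotion-averaged scores untouched).
    """
    rng = np.random.default_rng(seed)
    R, names = build_copula_correlation(config.spearman_targets)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(names)))
    n = config.n_subjects
    Z = rng.standard_normal((n, len(names))) @ L.T
    z = pd.DataFrame(Z, columns=names)

    subject_ids = [f"S{i:04d}" for i in range(n)]
    factors = z[list(FACTORS)].copy()
    factors.index = subject_ids
    propensities = z[list(COMPONENTS)].copy()
    propensities.index = subject_ids
    ratings = z[list(RATING_QUESTIONS)].copy()
    ratings.index = subject_ids

    lam = config.idio_max * norm.cdf(z["idiosyncrasy"].to_numpy())

    n_e, n_k = len(EMOTIONS), len(COMPONENTS)
    u = rng.standard_normal((n, n_e, n_k))
    u -= u.mean(axis=1, keepdims=True)  # centered across emotions per subject
    eta = rng.standard_normal((n, n_e, n_k))
    scores = (
        EMOTION_PROFILE[None, :, :]
        + config.sigma_propensity * propensities.to_numpy()[:, None, :]
        + lam[:, None, None] * u
        + config.sigma_within * eta
    )
    return LatentState(
        subject_ids=subject_ids,
        personality_factors=factors,
        map_propensities=propensities,
        map_scores=scores,
        idiosyncrasy_weight=lam,
        rating_latents=ratings,
        copula_spec=dict(config.spearman_targets),
    )


# ---------------------------------------------------------------------------
# maps


def _idiopatterns(
    mask: BodyMask, n: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Subject-specific smooth unit-norm rasters, vectorized (n x P)."""
    out = np.empty((n, mask.n_pixels))
    for i in range(n):
        field_ = gaussian_filter(
            rng.standard_normal((mask.height, mask.width)), sigma=sigma, mode="constant"
        )
        vec = mask.vectorize(field_)
        out[i] = vec / np.linalg.norm(vec)
    return out


def render_subject_maps(
    latents: LatentState,
    templates: TemplateSet,
    pixel_noise_sd: float = 0.02,
    idiosyncrasy_scale: float = 0.5,
    idio_smooth_sigma: float = 4.0,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render signed sensation maps (S x E x P) from the latent state.

    map(s, e) = clip(sum_k score(s,e,k) template_k
                     + lambda_s * scale * idiopattern_s + eps, -1, 1).
    """
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be >= 0")
    rng = np.random.default_rng(rng)
    mask = templates.mask
    scores = latents.map_scores
    n, n_e, _ = scores.shape
    maps = np.einsum("sek,kp->sep", scores, templates.values)
    if idiosyncrasy_scale > 0:
        patterns = _idiopatterns(mask, n, idio_smooth_sigma, rng)
        maps += (
            latents.idiosyncrasy_weight[:, None, None]
            * idiosyncrasy_scale
            * patterns[:, None, :]
        )
    if pixel_noise_sd > 0:
        maps += pixel_noise_sd * rng.standard_normal(maps.shape)
    np.clip(maps, -1.0, 1.0, out=maps)
    return maps


# ---------------------------------------------------------------------------
# questionnaires


def _likert(x: np.ndarray, levels: int) -> np.ndarray:
    """Round-and-clip discretization of a centered continuous score."""
    mid = (levels + 1) / 2.0
    return np.clip(np.rint(mid + x), 1, levels).astype(int)


def generate_questionnaires(
    latents: LatentState,
    scales: tuple = DEFAULT_SCALES,
    n_items_per_scale: int = 8,
    n_reversed_items: int = 2,
    noise_sd: float = 0.4,
    slope: float = 0.9,
    likert_levels: int = 5,
    rng: int | np.random.Generator = 0,
) -> QuestionnaireData:
    """Item-level Likert battery from the factor model.

    Each scale's true score is lambda * factor + sqrt(1 - lambda^2) * unique;
    item j discretizes slope * (true score + noise) shifted by a fixed
    per-item difficulty offset (evenly spread over the scale's items, so the
    keyed sum is a fine-grained staircase of the true score rather than a
    coarse 5-level one); scale scores are keyed item sums (reverse-keyed
    items contribute levels + 1 - response).
    """
    if likert_levels < 2:
        raise ValueError("Likert range must have at least 2 levels")
    if n_items_per_scale < 3:
        raise ValueError("need at least 3 items per scale")
    rng = np.random.default_rng(rng)
    F = latents.personality_factors.to_numpy()
    n = F.shape[0]
    factor_idx = {f: i for i, f in enumerate(FACTORS)}

    loadings = pd.DataFrame(
        0.0, index=[s for s, _, _ in scales], columns=list(FACTORS)
    )
    true_scores = {}
    items = {}
    keys = {}
    for scale_name, factor, lam in scales:
        loadings.loc[scale_name, factor] = lam
        unique = rng.standard_normal(n)
        t = lam * F[:, factor_idx[factor]] + math.sqrt(max(0.0, 1 - lam**2)) * unique
        true_scores[scale_name] = t
        difficulty = np.linspace(-1.2, 1.2, n_items_per_scale)
        for j in range(n_items_per_scale):
            reversed_ = j < n_reversed_items
            e = rng.standard_normal(n) if noise_sd > 0 else 0.0
            latent_item = slope * (t + noise_sd * e)
            if reversed_:
                latent_item = -latent_item
            col = f"{scale_name}__i{j}"
            items[col] = _likert(latent_item + difficulty[j], likert_levels)
            keys[col] = -1 if reversed_ else 1

    item_df = pd.DataFrame(items, index=latents.subject_ids)
    key_s = pd.Series(keys)
    # keyed sums: reverse-keyed items are reflected before summing
    reflected = item_df.copy()
    rev_cols = key_s.index[key_s == -1]
    reflected[rev_cols] = likert_levels + 1 - reflected[rev_cols]
    scale_of = {c: c.rsplit("__", 1)[0] for c in item_df.columns}
    scale_scores = reflected.T.groupby(scale_of).sum().T[list(loadings.index)]
    return QuestionnaireData(
        item_responses=item_df,
        scale_scores=scale_scores,
        scale_factor_loadings=loadings,
        true_scale_scores=pd.DataFrame(true_scores, index=latents.subject_ids),
        item_keys=key_s,
    )


# ---------------------------------------------------------------------------
# ratings


def generate_ratings(
    latents: LatentState,
    noise_sd: float = 0.4,
    slope: float = 0.8,
    likert_levels: int = 5,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-emotion 5-question experience ratings on a Likert scale.

    rating(s, e, q) discretizes slope * latent_q(s) + offset(e, q) + noise.
    """
    rng = np.random.default_rng(rng)
    lat = latents.rating_latents.to_numpy()  # n x 5
    n = lat.shape[0]
    vals = (
        slope * lat[:, None, :]
        + RATING_OFFSETS[None, :, :]
        + noise_sd * rng.standard_normal((n, len(EMOTIONS), len(RATING_QUESTIONS)))
    )
    resp = _likert(vals, likert_levels)
    index = pd.MultiIndex.from_product(
        [latents.subject_ids, EMOTIONS], names=["subject", "emotion"]
    )
    return pd.DataFrame(
        resp.reshape(-1, len(RATING_QUESTIONS)), index=index, columns=RATING_QUESTIONS
    )


# ---------------------------------------------------------------------------
# non-compliance


def inject_noncompliance(
    dataset: StudyDataset,
    frac_random_responders: float = 0.05,
    frac_empty_map_subjects: float = 0.05,
    rng: int | np.random.Generator = 0,
) -> StudyDataset:
    """Plant non-compliant subjects; ground truth goes to noncompliance_flags.

    Random responders get iid uniform Likert item responses; empty-map
    subjects get 3-5 all-zero maps. Counts are round(frac * n) each, on
    disjoint subject sets.
    """
    fr, fe = frac_random_responders, frac_empty_map_subjects
    if not (0 <= fr < 1 and 0 <= fe < 1):
        raise ValueError("fractions must lie in [0, 1)")
    if fr + fe >= 1:
        raise ValueError("noncompliance fractions must sum to < 1")
    rng = np.random.default_rng(rng)
    n = len(dataset.subject_ids)
    n_rand = int(round(fr * n))
    n_empty = int(round(fe * n))
    if n_rand + n_empty == 0:
        return replace(
            dataset,
            noncompliance_flags=pd.DataFrame(columns=["subject_id", "kind"]),
        )
    chosen = rng.choice(n, size=n_rand + n_empty, replace=False)
    rand_idx, empty_idx = chosen[:n_rand], chosen[n_rand:]

    items = dataset.questionnaire.item_responses.copy()
    levels = int(items.to_numpy().max())
    for i in rand_idx:
        items.iloc[i, :] = rng.integers(1, levels + 1, size=items.shape[1])
    q = replace(dataset.questionnaire, item_responses=items)
    # keyed sums must stay consistent with the overwritten items
    reflected = items.copy()
    rev = q.item_keys.index[q.item_keys == -1]
    reflected[rev] = levels + 1 - reflected[rev]
    scale_of = {c: c.rsplit("__", 1)[0] for c in items.columns}
    q = replace(
        q,
        scale_scores=reflected.T.groupby(scale_of).sum().T[
            list(q.scale_scores.columns)
        ],
    )

    maps = dataset.maps.copy()
    for i in empty_idx:
        k = int(rng.integers(3, 6))
        emos = rng.choice(len(EMOTIONS), size=k, replace=False)
        maps[i, emos, :] = 0.0

    flags = pd.DataFrame(
        {
            "subject_id": [dataset.subject_ids[i] for i in chosen],
            "kind": ["random_responder"] * n_rand + ["empty_maps"] * n_empty,
        }
    )
    return replace(dataset, questionnaire=q, maps=maps, noncompliance_flags=flags)


# ---------------------------------------------------------------------------
# full study


def generate_study(config: GeneratorConfig, seed: int) -> StudyDataset:
    """Generate one complete synthetic study, deterministically from the seed."""
    from ._utils import substream

    mask = build_manikin_mask(config.mask_height, config.mask_width)
    templates = build_component_templates(mask)
    latents = sample_cohort_latents(config, substream(seed, "latents"))
    maps = render_subject_maps(
        latents,
        templates,
        pixel_noise_sd=config.pixel_noise_sd,
        idiosyncrasy_scale=config.idio_raster_scale,
        idio_smooth_sigma=config.idio_smooth_sigma,
        rng=substream(seed, "render"),
    )
    questionnaire = generate_questionnaires(
        latents,
        scales=config.scales,
        n_items_per_scale=config.n_items_per_scale,
        n_reversed_items=config.n_reversed_items,
        noise_sd=config.item_noise_sd,
        slope=config.item_slope,
        likert_levels=config.likert_levels,
        rng=substream(seed, "items"),
    )
    ratings = generate_ratings(
        latents,
        noise_sd=config.rating_noise_sd,
        slope=config.rating_slope,
        likert_levels=config.likert_levels,
        rng=substream(seed, "ratings"),
    )
    ds = StudyDataset(
        mask=mask,
        templates=templates,
        subject_ids=latents.subject_ids,
        maps=maps,
        questionnaire=questionnaire,
        ratings=ratings,
        latents=latents,
        noncompliance_flags=pd.DataFrame(columns=["subject_id", "kind"]),
    )
    if config.frac_random_responders > 0 or config.frac_empty_map_subjects > 0:
        ds = inject_noncompliance(
            ds,
            config.frac_random_responders,
            config.frac_empty_map_subjects,
            rng=substream(seed, "noncompliance"),
        )
    return ds


# ---------------------------------------------------------------------------
# calibration


def calibrate_idiosyncrasy_link(
    target_rho: float = -0.18,
    factor: str = "antisocial",
    config: GeneratorConfig | None = None,
    n_cohorts: int = 20,
    seed: int = 0,
) -> float:
    """Monte-Carlo calibration of the idiosyncrasy-driver copula link.

    Representativeness is a derived statistic, so its correlation with a
    personality factor cannot be planted directly. This utility measures the
    rank correlation between representativeness (computed on the true
    component scores) and the idiosyncrasy driver, then returns the driver ~
    factor copula correlation needed so the measured representativeness ~
    factor Spearman lands on ``target_rho``. The returned value is what the
    generator defaults freeze.
    """
    from .granularity import representativeness_score

    config = config or GeneratorConfig()
    # decouple the driver from the factors so the chain alone is measured
    targets = {
        k: v for k, v in config.spearman_targets.items() if k[0] != "idiosyncrasy"
    }
    cfg = replace(config, spearman_targets=targets)
    chain = []
    path0 = []
    for c in range(n_cohorts):
        lat = sample_cohort_latents(cfg, np.random.default_rng([seed, c]))
        # the pipeline measures representativeness in grand-mean-centered
        # component space; mirror that here
        sc = lat.map_scores - lat.map_scores.mean(axis=(0, 1), keepdims=True)
        group_mean = sc.mean(axis=0)  # E x K
        rep = np.array(
            [
                representativeness_score(sc[i], group_mean)
                for i in range(len(lat.subject_ids))
            ]
        )
        chain.append(spearmanr(rep, lat.idiosyncrasy_weight).statistic)
        path0.append(
            spearmanr(rep, lat.personality_factors[factor]).statistic
        )
    mean_chain = float(np.mean(chain))  # rank corr of representativeness vs driver
    if abs(mean_chain) < 1e-6:
        raise RuntimeError("idiosyncrasy has no measurable effect; increase idio_max")
    # the factor also reaches representativeness through its planted component
    # propensities; the driver link only needs to supply the remainder
    rho = (target_rho - float(np.mean(path0))) / mean_chain
    return float(np.clip(rho, -0.95, 0.95))
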
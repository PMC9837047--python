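"""Classifier-based emotional granularity and cosine pattern metrics.

Emotions are classified from body-map component scores with a pooled-
covariance Gaussian (linear discriminant) classifier using empirical class
priors. Three per-subject metrics follow:

* confidence — mean posterior probability assigned to the true emotion label
  over the subject's maps (a proxy for emotional granularity);
* differentiation — mean pairwise cosine distance among the subject's
  emotion score-vectors (how distinct the emotions feel);
* representativeness — mean cosine similarity between the subject's
  per-emotion score-vector and the group-average vector for that emotion
  (how typical the subject's maps are).

A Sobel test quantifies whether a personality-differentiation association is
mediated by representativeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._utils import cosine_similarity, pairwise_mean_cosine_distance

__all__ = [
    "ClassifierModel",
    "GranularityMetrics",
    "fit_lda",
    "classifier_significance",
    "chi2_from_counts",
    "confidence_scores",
    "confidence_scores_cv",
    "differentiation_score",
    "representativeness_score",
    "granularity_metrics",
    "sobel_z",
    "sobel_mediation",
]

log = logging.getLogger(__name__)


@dataclass
class ClassifierModel:
    """Pooled-covariance Gaussian classifier (LDA) with empirical priors."""

    estimator: LinearDiscriminantAnalysis
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray  # class x feature
    pooled_covariance: np.ndarray
    regularized: bool

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Class posterior probabilities, proportional to prior x N(x; mu_c, Sigma)."""
        return self.estimator.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


@dataclass
class GranularityMetrics:
    """Per-subject confidence, differentiation and representativeness."""

    table: pd.DataFrame  # index subject_id; columns confidence/differentiation/representativeness


def fit_lda(X: np.ndarray, labels: np.ndarray) -> ClassifierModel:
    """Fit the pooled-covariance Gaussian classifier with empirical priors.

    Falls back to auto-shrinkage regularization of the pooled covariance when
    it is singular (logged).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 observations per class")
    regularized = False
    est = LinearDiscriminantAnalysis(solver="svd", store_covariance=True)
    est.fit(X, labels)
    cov = est.covariance_
    # singular pooled covariance: refit with shrinkage
    if np.linalg.matrix_rank(cov) < cov.shape[0] or not np.all(
        np.linalg.eigvalsh(cov) > 1e-12
    ):
        log.warning("singular pooled covariance; applying auto-shrinkage")
        est = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto", store_covariance=True
        )
        est.fit(X, labels)
        cov = est.covariance_
        regularized = True
    return ClassifierModel(
        estimator=est,
        classes=est.classes_,
        priors=est.priors_,
        means=est.means_,
        pooled_covariance=cov,
        regularized=regularized,
    )


def chi2_from_counts(n_correct: int, n_total: int, chance: float = 0.10) -> float:
    """Goodness-of-fit chi-square of (correct, incorrect) counts vs chance."""
    e1 = chance * n_total
    e0 = (1 - chance) * n_total
    return float((n_correct - e1) ** 2 / e1 + ((n_total - n_correct) - e0) ** 2 / e0)


def classifier_significance(
    X: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    n_splits: int = 1000,
    chance: float = 0.10,
    seed: int | np.random.Generator = 0,
    split_by_subject: bool = True,
) -> dict:
    """Full-fit accuracy/confusion plus split-half cross-validated p value.

    The parametric test is a goodness-of-fit chi-square of the full-data
    refit (correct, incorrect) counts against the chance proportion. The
    cross-validation p value is the fraction of ``n_splits`` random half/half
    splits whose test accuracy falls at or below chance, floored at
    1/n_splits. Splits are by subject (all of a subject's maps on one side)
    unless ``split_by_subject`` is False.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)

    model = fit_lda(X, labels)
    pred = model.predict(X)
    acc = float(np.mean(pred == labels))
    classes = model.classes
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(labels, pred):
        confusion.loc[t, p] += 1
    chi2_stat = chi2_from_counts(int((pred == labels).sum()), len(labels), chance)
    p_param = float(chi2.sf(chi2_stat, df=1))

    accs = []
    redrawn = 0
    units = np.unique(subjects) if split_by_subject else np.arange(len(labels))
    for _ in range(n_splits):
        while True:
            perm = rng.permutation(len(units))
            half = len(units) // 2
            train_units = set(units[perm[:half]])
            if split_by_subject:
                tr = np.isin(subjects, list(train_units))
            else:
                tr = np.zeros(len(labels), dtype=bool)
                tr[perm[:half]] = True
            if set(labels[tr]) == set(classes) and set(labels[~tr]) == set(classes):
                break
            redrawn += 1
            if redrawn > 100 * max(n_splits, 1):
                raise RuntimeError("cannot draw splits containing every class")
        m = fit_lda(X[tr], labels[tr])
        accs.append(float(np.mean(m.predict(X[~tr]) == labels[~tr])))
    if redrawn:
        log.info("%d splits redrawn for missing classes", redrawn)
    p_cv = None
    if n_splits > 0:
        p_cv = max(float(np.mean(np.asarray(accs) <= chance)), 1.0 / n_splits)
    return {
        "accuracy": acc,
        "confusion": confusion,
        "chi2": chi2_stat,
        "p_param": p_param,
        "p_cv": p_cv,
        "cv_accuracies": np.asarray(accs),
    }


def confidence_scores(
    model: ClassifierModel,
    X: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
) -> pd.Series:
    """Per-subject mean posterior probability of the true emotion label."""
    post = model.posterior(X)
    class_idx = {c: i for i, c in enumerate(model.classes)}
    p_true = post[np.arange(len(labels)), [class_idx[c] for c in labels]]
    return (
        pd.Series(p_true, index=pd.Index(subjects, name="subject"), name="confidence")
        .groupby(level=0, sort=False)
        .mean()
    )


def confidence_scores_cv(
    X: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Leakage-free confidence: posteriors from subject-wise cross-validation.

    Subjects are split into ``n_folds`` folds; each subject's posteriors come
    from a model fit on the other folds.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)
    units = np.unique(subjects)
    order = rng.permutation(len(units))
    folds = np.array_split(units[order], n_folds)
    parts = []
    for fold in folds:
        held = np.isin(subjects, fold)
        model = fit_lda(X[~held], labels[~held])
        parts.append(
            confidence_scores(model, X[held], labels[held], subjects[held])
        )
    return pd.concat(parts).sort_index()


def differentiation_score(subject_scores: np.ndarray) -> float:
    """Mean pairwise cosine distance among a subject's emotion vectors.

    Zero vectors (empty maps) are skipped with the denominator adjusted.
    """
    V = np.asarray(subject_scores, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 emotion vectors")
    return pairwise_mean_cosine_distance(V)


def representativeness_score(
    subject_scores: np.ndarray, group_mean_scores: np.ndarray
) -> float:
    """Mean cosine similarity of subject emotion vectors to the group means.

    Emotions where either vector is zero are skipped, adjusting the
    denominator.
    """
    V = np.asarray(subject_scores, dtype=float)
    G = np.asarray(group_mean_scores, dtype=float)
    if V.shape != G.shape:
        raise ValueError("subject and group score shapes differ")
    sims = [cosine_similarity(v, g) for v, g in zip(V, G)]
    sims = [s for s in sims if not np.isnan(s)]
    if not sims:
        return float("nan")
    return float(np.mean(sims))


def granularity_metrics(
    scores: pd.DataFrame,
    model: ClassifierModel | None = None,
    leave_one_out: bool = False,
) -> GranularityMetrics:
    """Confidence, differentiation and representativeness for every subject.

    ``scores`` is keyed by a (subject, emotion) MultiIndex with component
    columns. By default the group-mean vectors include all subjects;
    ``leave_one_out`` excludes each subject from their own reference means.
    Confidence requires a fitted classifier; without one the column is NaN.
    """
    subjects = scores.index.get_level_values(0)
    emotions = scores.index.get_level_values(1)
    group_sum = scores.groupby(level=1, sort=False).sum()
    group_n = scores.groupby(level=1, sort=False).size()
    group_mean = group_sum.div(group_n, axis=0)
    rows = {}
    for s in subjects.unique():
        sub = scores.xs(s, level=0)
        if leave_one_out:
            G = (
                (group_sum.loc[sub.index] - sub)
                .div(group_n.loc[sub.index] - 1, axis=0)
                .to_numpy()
            )
        else:
            G = group_mean.loc[sub.index].to_numpy()
        rows[s] = {
            "differentiation": differentiation_score(sub.to_numpy()),
            "representativeness": representativeness_score(sub.to_numpy(), G),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "subject"
    if model is not None:
        conf = confidence_scores(
            model, scores.to_numpy(), emotions.to_numpy(), subjects.to_numpy()
        )
        table["confidence"] = conf
    else:
        table["confidence"] = np.nan
    return GranularityMetrics(
        table=table[["confidence", "differentiation", "representativeness"]]
    )


def sobel_z(a: float, se_a: float, b: float, se_b: float) -> float:
    """Sobel delta-method z statistic of the indirect effect a*b."""
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    return 0.0 if denom == 0 else float(a * b / denom)


def sobel_mediation(x: np.ndarray, mediator: np.ndarray, y: np.ndarray) -> dict:
    """Sobel test of the indirect effect x -> mediator -> y.

    a is the slope of mediator ~ x; b the slope of y ~ mediator + x;
    z = a b / sqrt(b^2 se_a^2 + a^2 se_b^2), two-sided normal p.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 complete triples")
    for name, v in (("x", x), ("mediator", m), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"zero-variance input: {name}")
    fit_a = sm.OLS(m, sm.add_constant(x)).fit()
    a, se_a = fit_a.params[1], fit_a.bse[1]
    fit_b = sm.OLS(y, sm.add_constant(np.column_stack([m, x]))).fit()
    b, se_b = fit_b.params[1], fit_b.bse[1]
    z = sobel_z(a, se_a, b, se_b)
    p = 1.0 if z == 0 else float(2 * norm.sf(abs(z)))
    return {"a": float(a), "b": float(b), "se_a": float(se_a), "se_b": float(se_b), "z": z, "p": p}
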
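"""Participant screening: robust multivariate outlier detection and the
map-completeness rule.

Random responders in the questionnaire battery are detected with a
forward-search ("Hadi") multivariate outlier procedure: a small basic subset
of observations is grown by smallest scaled Mahalanobis distance to the
subset mean/covariance until the next candidate exceeds a chi-square cutoff;
everything outside the final subset-consistent distance cutoff is flagged.
Because batteries can have more items than subjects, the screen is repeated
on random item subsets and a subject is removed when flagged in more than a
threshold fraction of repetitions.

Subjects who leave three or more of their ten emotion maps completely empty
are removed by the completeness rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as fdist

__all__ = ["ScreeningReport", "hadi_flag", "repeated_subset_screen", "completeness_screen"]

log = logging.getLogger(__name__)


@dataclass
class ScreeningReport:
    """Removed subjects with reasons, plus per-subject Hadi flag rates."""

    removed: pd.DataFrame  # columns: subject_id, reason
    flag_rate: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def removed_ids(self) -> set:
        return set(self.removed["subject_id"])

    @staticmethod
    def union(*reports: "ScreeningReport") -> "ScreeningReport":
        removed = pd.concat(
            [r.removed for r in reports], ignore_index=True
        ).drop_duplicates()
        rates = [r.flag_rate for r in reports if len(r.flag_rate)]
        return ScreeningReport(
            removed=removed,
            flag_rate=rates[0] if rates else pd.Series(dtype=float),
        )


def _truncation_factor(r: int, n: int, p: int) -> float:
    """Fisher-consistency factor for the covariance of the r/n most central
    points of a p-variate normal sample: kappa = F_{chi2(p+2)}(q_{r/n}) / (r/n),
    which is < 1; raw squared distances are multiplied by it."""
    frac = r / n
    if frac >= 1.0:
        return 1.0
    q = chi2.ppf(frac, p)
    return float(chi2.cdf(q, p + 2) / frac)


def _distance_cutoff(r: int, p: int, n: int, alpha: float) -> float:
    """Squared-distance cutoff for points judged against a subset of size r.

    The tail probability is alpha/n (the forward-search algorithm's published
    simultaneous form, which controls the chance that any clean observation
    is flagged). For an observation outside the estimation subset the scaled
    Mahalanobis distance follows (p (r+1)(r-1)) / (r (r-p)) * F(p, r-p)
    rather than chi-square; the F form matters when p approaches n (as in
    item-level screens) and converges to the chi-square quantile for r >> p.
    """
    tail = alpha / n
    dfree = r - p
    if dfree >= 2:
        c_out = p * (r + 1) * (r - 1) / (r * (r - p))
        return float(c_out * fdist.ppf(1.0 - tail, p, dfree))
    return float(chi2.ppf(1.0 - tail, p))


def _mahalanobis_sq(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    from scipy.linalg import cho_factor, cho_solve, LinAlgError

    D = X - mean
    try:
        c = cho_factor(cov, lower=True)
    except LinAlgError:
        raise np.linalg.LinAlgError("singular subset covariance")
    return np.einsum("ij,ji->i", D, cho_solve(c, D.T))


def hadi_flag(X: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Forward-search multivariate outlier flags for the rows of X.

    Starts from the p + 1 observations closest (in Mahalanobis distance about
    the coordinatewise median) to the bulk, grows the basic subset by
    smallest scaled distance to the subset mean/covariance — corrected by the
    truncation consistency factor — and stops once the subset holds a
    majority and the next candidate's squared distance exceeds the
    1 - alpha/n quantile of the out-of-subset distance law (an F form with p
    and r - p degrees of freedom that converges to the chi-square(p)
    quantile for large subsets; the alpha/n adjustment is the algorithm's
    published simultaneous form). Rows beyond the cutoff are flagged.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(
            f"need n_subjects > n_variables + 1 (got n={n}, p={p}); "
            "screen on fewer variables"
        )
    med = np.median(X, axis=0)
    D0 = X - med
    C0 = (D0.T @ D0) / (n - 1)
    try:
        d0 = _mahalanobis_sq(X, med, C0)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular covariance about the median; use fewer variables"
        )
    order = np.argsort(d0, kind="stable")
    r = p + 1
    majority = (n + p + 1) // 2
    while True:
        subset = order[:r]
        mean = X[subset].mean(axis=0)
        cov = np.cov(X[subset], rowvar=False)
        try:
            d2 = _mahalanobis_sq(X, mean, cov) * _truncation_factor(r, n, p)
        except np.linalg.LinAlgError:
            if r < n:
                r += 1
                continue
            raise np.linalg.LinAlgError(
                "singular subset covariance; use fewer variables"
            )
        cutoff = _distance_cutoff(r, p, n, alpha)
        order = np.argsort(d2, kind="stable")
        if r >= n:
            break
        if r >= majority and d2[order[r]] > cutoff:
            break
        r += 1
    return d2 > cutoff


def repeated_subset_screen(
    items: pd.DataFrame,
    n_reps: int = 1000,
    subset_frac: float = 0.5,
    alpha: float = 0.05,
    removal_threshold: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> ScreeningReport:
    """Repeated Hadi screen on random item subsets.

    Each repetition runs the forward search on a random ``subset_frac``
    fraction of the items; a subject is removed when flagged in more than
    ``removal_threshold`` of the repetitions. When the item subset would
    leave p >= n - 1 (small cohorts), the subset size is capped at
    0.8 * n_subjects items (logged).
    """
    rng = np.random.default_rng(seed)
    X = items.to_numpy(dtype=float)
    n, p_total = X.shape
    n_sel = int(round(subset_frac * p_total))
    cap = min(int(0.8 * n), n - 2)
    if n_sel > cap:
        log.info("capping Hadi item subset at %d of %d items (n=%d)", cap, p_total, n)
        n_sel = cap
    if n_sel < 2:
        raise ValueError(
            f"cannot screen: n={n} too small for any usable item subset"
        )
    counts = np.zeros(n)
    rep = 0
    attempts = 0
    while rep < n_reps:
        if attempts > 20 * n_reps:
            raise RuntimeError("too many singular Hadi repetitions; reduce items")
        attempts += 1
        cols = rng.choice(p_total, size=n_sel, replace=False)
        try:
            flags = hadi_flag(X[:, cols], alpha=alpha)
        except np.linalg.LinAlgError:
            log.debug("singular repetition redrawn")
            continue
        counts += flags
        rep += 1
    rate = pd.Series(counts / n_reps, index=items.index, name="flag_rate")
    removed_ids = rate.index[rate > removal_threshold]
    removed = pd.DataFrame(
        {"subject_id": list(removed_ids), "reason": "random_responder"}
    )
    return ScreeningReport(removed=removed, flag_rate=rate)


def completeness_screen(
    maps: np.ndarray,
    subject_ids: list,
    min_empty: int = 3,
    available: np.ndarray | None = None,
) -> ScreeningReport:
    """Remove subjects with ``min_empty`` or more entirely empty maps.

    ``maps`` is S x E x P; a map is empty when all its values are exactly
    zero. Missing emotion entries (``available`` False) count as empty.
    """
    maps = np.asarray(maps)
    empty = ~np.any(maps != 0, axis=2)
    if available is not None:
        missing = ~np.asarray(available, dtype=bool)
        if missing.any():
            log.warning("%d missing emotion entries treated as empty", missing.sum())
        empty |= missing
    n_empty = empty.sum(axis=1)
    removed = pd.DataFrame(
        {
            "subject_id": [s for s, k in zip(subject_ids, n_empty) if k >= min_empty],
            "reason": "incomplete_maps",
        }
    )
    return ScreeningReport(removed=removed)
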
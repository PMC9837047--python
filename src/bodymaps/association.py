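"""Spearman association tables, pixelwise t-maps and extreme-group maps.

Personality and body-map component scores are correlated with Spearman's
rank correlation; the table of all component pairs is corrected with the
Benjamini-Hochberg false discovery rate. Validation ("salience") tables
correlate body-map components with subjective body/mind ratings.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "emotion_average_scores",
    "spearman_fdr",
    "pixel_t_map",
    "extreme_group_maps",
    "salience_correlations",
]

log = logging.getLogger(__name__)


def emotion_average_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over emotions of (subject, emotion)-keyed scores.

    Missing emotions simply drop out of a subject's mean (logged).
    """
    if not isinstance(scores.index, pd.MultiIndex):
        raise ValueError("scores must be keyed by a (subject, emotion) MultiIndex")
    counts = scores.groupby(level=0).size()
    if counts.nunique() > 1:
        log.info(
            "unequal emotion counts per subject (%d..%d); averaging available maps",
            counts.min(),
            counts.max(),
        )
    return scores.groupby(level=0, sort=False).mean()


def _spearman_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    if n < 20:
        # small samples: permutation p (exact when enumerable)
        def statistic(x):
            return stats.spearmanr(x, b).statistic

        rho = float(stats.spearmanr(a, b).statistic)
        res = stats.permutation_test(
            (a,),
            statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=20000,
            rng=0,
        )
        return rho, float(res.pvalue)
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def spearman_fdr(A: pd.DataFrame, B: pd.DataFrame, fdr: bool = True) -> pd.DataFrame:
    """Spearman correlations of every column pair of A x B, BH-corrected.

    Returns a tidy table with columns (var_a, var_b, n, rho, p, p_fdr,
    significant_at_0.05). Constant columns yield NaN rho with a logged
    reason; those cells are excluded from the BH family.
    """
    common = A.index.intersection(B.index)
    rows = []
    for ca in A.columns:
        for cb in B.columns:
            a = A.loc[common, ca].to_numpy(dtype=float)
            b = B.loc[common, cb].to_numpy(dtype=float)
            keep = ~(np.isnan(a) | np.isnan(b))
            rho, p = _spearman_pair(a[keep], b[keep])
            if math.isnan(rho):
                log.warning("constant column in pair (%s, %s); rho undefined", ca, cb)
            rows.append({"var_a": ca, "var_b": cb, "n": int(keep.sum()), "rho": rho, "p": p})
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    ok = table["p"].notna()
    if fdr and ok.any():
        _, p_adj, _, _ = multipletests(table.loc[ok, "p"], method="fdr_bh")
        table.loc[ok, "p_fdr"] = p_adj
    crit = table["p_fdr"] if fdr else table["p"]
    table["significant_at_0.05"] = crit < 0.05
    return table


def pixel_t_map(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t statistic against zero at each pixel.

    ``maps`` is n_subjects x P for one emotion. Returns (t, undefined) where
    zero-variance pixels get t = 0 with the undefined flag set.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = maps.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_1samp(maps, 0.0, axis=0).statistic
    t = np.where(undefined, 0.0, t)
    return t, undefined


def extreme_group_maps(
    component_scores: pd.Series,
    maps: np.ndarray,
    subject_ids: list,
    pct: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise mean maps of the bottom and top pct% scorers.

    Group size is ceil(pct% * n); score ties break by subject id for
    determinism. Means are taken across subjects and emotions. Returns
    (bottom_map, top_map) as vectors over inside pixels.
    """
    if not (0 < pct <= 50):
        raise ValueError("pct must lie in (0, 50]")
    scores = component_scores.loc[list(subject_ids)].to_numpy(dtype=float)
    n = len(subject_ids)
    g = math.ceil(pct / 100.0 * n)
    order = np.lexsort((np.asarray(subject_ids), scores))
    bottom, top = order[:g], order[-g:]
    maps = np.asarray(maps)
    return maps[bottom].mean(axis=(0, 1)), maps[top].mean(axis=(0, 1))


def salience_correlations(
    avg_component_scores: pd.DataFrame,
    avg_ratings: pd.DataFrame,
    questions: tuple[str, ...] = ("body", "mind"),
    fdr: bool = False,
) -> pd.DataFrame:
    """Correlations of emotion-averaged components with salience ratings.

    Reported uncorrected by default, mirroring how validation correlations
    are usually presented; pass ``fdr=True`` to correct the table.
    """
    return spearman_fdr(avg_component_scores, avg_ratings[list(questions)], fdr=fdr)
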
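"""PCA with sign-flip permutation retention, quartimax rotation, and
bootstrap loading z-scores.

The map matrix (individual emotion maps as observations, silhouette pixels as
variables) and the personality scale matrix (subjects as observations, scales
as variables) are both reduced with the same machinery:

* plain PCA via singular values (covariance PCA for maps, which share pixel
  units; correlation PCA for scales, which do not);
* component retention by a parallel-analysis variant in which the null
  eigenvalue envelope comes from elementwise random sign-flips of the
  (centered, optionally standardized) data matrix — robust to heterogeneous
  noise across variables;
* quartimax rotation of the retained components for interpretability;
* loading standard errors by bootstrap resampling of observations, with each
  bootstrap solution aligned to the reference by Tucker congruence before
  accumulating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "ComponentModel",
    "RetentionResult",
    "BootstrapLoadings",
    "fit_pca",
    "signflip_retention",
    "quartimax_rotate",
    "quartimax_criterion",
    "apply_sign_convention",
    "rotate_model",
    "tucker_congruence",
    "match_components",
    "bootstrap_loading_z",
]


@dataclass
class ComponentModel:
    """Loadings, eigenvalues, rotation and scores of one PCA.

    ``loadings`` are unit-norm eigenvector columns (variables x K), rotated in
    place when a rotation has been applied; ``rotation`` is the orthogonal
    K x K matrix mapping the unrotated solution onto ``loadings``;
    ``eigenvalues`` are the pre-rotation variances (descending).
    """

    loadings: np.ndarray  # variables x K
    eigenvalues: np.ndarray  # K, pre-rotation, descending
    rotation: np.ndarray  # K x K orthogonal
    scores: np.ndarray  # observations x K
    center: np.ndarray  # per-variable mean removed
    scale: np.ndarray | None  # per-variable SD divided out (correlation PCA)
    variable_ids: list
    observation_keys: list

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def rotated_variance(self) -> np.ndarray:
        """Variance of each (rotated) component's scores."""
        return self.scores.var(axis=0, ddof=1)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new observations into the (rotated) component space."""
        Xc = np.asarray(X, dtype=float) - self.center
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc @ self.loadings


@dataclass
class RetentionResult:
    """Observed eigenvalues against the sign-flip permutation envelope."""

    observed_eigenvalues: np.ndarray
    envelope: np.ndarray  # per-rank percentile of the permutation distribution
    permutation_median: np.ndarray
    n_retained: int
    n_permutations: int
    percentile: float


@dataclass
class BootstrapLoadings:
    """Bootstrap SDs and z-scores of rotated loadings."""

    loading_sd: np.ndarray  # variables x K
    z: np.ndarray  # variables x K; NaN where sd == 0
    undefined: np.ndarray  # bool mask of sd == 0 cells
    n_boot: int
    n_resampled: int  # bootstrap draws redrawn (zero-variance variable)


def _preprocess(
    X: np.ndarray, center: bool, scale: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance variables with scale=True at columns {dead.tolist()}"
            )
        Xc = Xc / sd
    return Xc, mu, sd


def fit_pca(
    X: np.ndarray,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
    variable_ids: list | None = None,
    observation_keys: list | None = None,
    random_state: int = 0,
) -> ComponentModel:
    """PCA of the (optionally standardized) centered matrix via SVD.

    Eigenvalues are squared singular values / (n_obs - 1). When
    ``n_components`` is given and much smaller than both matrix dimensions, a
    randomized truncated SVD is used.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    Xc, mu, sd = _preprocess(X, center, scale)
    k_max = min(n, p)
    k = k_max if n_components is None else min(n_components, k_max)
    if n_components is not None and k < 0.25 * k_max and min(n, p) > 50:
        U, s, Vt = randomized_svd(
            Xc, n_components=k, n_oversamples=10, random_state=random_state
        )
    else:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    eig = s**2 / (n - 1)
    return ComponentModel(
        loadings=Vt.T.copy(),
        eigenvalues=eig,
        rotation=np.eye(k),
        scores=Xc @ Vt.T,
        center=mu,
        scale=sd,
        variable_ids=list(variable_ids) if variable_ids is not None else list(range(p)),
        observation_keys=(
            list(observation_keys) if observation_keys is not None else list(range(n))
        ),
    )


def signflip_retention(
    X: np.ndarray,
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
    center: bool = True,
    scale: bool = False,
) -> RetentionResult:
    """Sign-flip parallel analysis for PCA component retention.

    Each permutation multiplies the preprocessed matrix elementwise by iid
    random +/-1 and recomputes the eigenvalue spectrum; a component is
    retained while its observed eigenvalue exceeds the per-rank envelope
    (counting contiguously from rank 1, stopping at the first failure).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20: envelope meaningless")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation envelope may be unstable")
    rng = np.random.default_rng(seed)
    Xc, _, _ = _preprocess(np.asarray(X, dtype=float), center, scale)
    n = Xc.shape[0]
    observed = np.linalg.svd(Xc, compute_uv=False) ** 2 / (n - 1)
    perm_eigs = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        flips = rng.integers(0, 2, size=Xc.shape) * 2.0 - 1.0
        perm_eigs[b] = np.linalg.svd(Xc * flips, compute_uv=False) ** 2 / (n - 1)
    envelope = np.percentile(perm_eigs, percentile, axis=0)
    med = np.median(perm_eigs, axis=0)
    exceeds = observed > envelope
    n_retained = int(np.argmin(exceeds)) if not exceeds.all() else int(exceeds.size)
    if not exceeds[0]:
        n_retained = 0
    return RetentionResult(
        observed_eigenvalues=observed,
        envelope=envelope,
        permutation_median=med,
        n_retained=n_retained,
        n_permutations=n_perm,
        percentile=percentile,
    )


def quartimax_criterion(loadings: np.ndarray) -> float:
    """Quartimax objective: sum of fourth powers of the loadings."""
    return float(np.sum(np.asarray(loadings) ** 4))


def quartimax_rotate(
    loadings: np.ndarray, tol: float = 1e-8, max_sweeps: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal quartimax rotation (maximizes the sum of fourth powers).

    Iterative pairwise (Jacobi-style) updates: for each pair of components
    the closed-form plane-rotation angle maximizing the fourth-power
    criterion is applied; sweeps repeat until the criterion improvement per
    sweep falls below ``tol``. The criterion is non-decreasing across
    iterations. Returns (rotated loadings, rotation matrix R) with
    rotated = loadings @ R and R orthogonal. K = 1 returns the input
    unchanged.
    """
    A = np.asarray(loadings, dtype=float)
    if A.ndim != 2:
        raise ValueError("loadings must be 2-D")
    K = A.shape[1]
    if K < 2:
        return A.copy(), np.eye(K)
    L = A.copy()
    R = np.eye(K)
    crit = quartimax_criterion(L)
    trace = [crit]
    for _ in range(max_sweeps):
        for i in range(K - 1):
            for j in range(i + 1, K):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = np.sum(2.0 * u * v)
                den = np.sum(u**2 - v**2)
                phi = -0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, s], [-s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        new = quartimax_criterion(L)
        trace.append(new)
        if new < crit - 1e-9:
            raise RuntimeError(
                f"quartimax criterion decreased; trace: {trace}"
            )
        if new - crit < tol:
            return L, R
        crit = new
    raise RuntimeError(
        f"quartimax failed to converge in {max_sweeps} sweeps; trace tail: "
        f"{trace[-5:]}"
    )


def apply_sign_convention(model: ComponentModel) -> ComponentModel:
    """Flip each component so its maximum-|loading| variable loads positively.

    Scores are flipped consistently. Removes the sign indeterminacy of PCA so
    downstream correlation signs are well defined.
    """
    L = model.loadings.copy()
    S = model.scores.copy()
    R = model.rotation.copy()
    for k in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, k])))
        if L[i, k] < 0:
            L[:, k] *= -1
            S[:, k] *= -1
            R[:, k] *= -1
    return replace(model, loadings=L, scores=S, rotation=R)


def rotate_model(model: ComponentModel) -> ComponentModel:
    """Quartimax-rotate a fitted model and apply the sign convention."""
    L, R = quartimax_rotate(model.loadings)
    rotated = replace(
        model,
        loadings=L,
        scores=model.scores @ R,
        rotation=model.rotation @ R,
    )
    return apply_sign_convention(rotated)


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruence coefficients between columns of A and B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (A.T @ B) / np.outer(na, nb)


def match_components(
    reference: np.ndarray, candidate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy column matching of candidate onto reference by |congruence|.

    Returns (permutation, signs) such that candidate[:, permutation] * signs
    best matches the reference columns; ties break toward the original column
    order.
    """
    C = tucker_congruence(reference, candidate)
    k_ref, k_cand = C.shape
    perm = np.full(k_ref, -1, dtype=int)
    signs = np.ones(k_ref)
    free = list(range(k_cand))
    # assign reference columns in order of their best available match strength
    order = np.argsort(-np.max(np.abs(C), axis=1), kind="stable")
    for i in order:
        j = max(free, key=lambda j: (abs(C[i, j]), -j))
        perm[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        free.remove(j)
    return perm, signs


def bootstrap_loading_z(
    X: np.ndarray,
    K: int,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    center: bool = True,
    scale: bool = False,
    reference_model: ComponentModel | None = None,
) -> BootstrapLoadings:
    """Bootstrap SDs and z-scores of quartimax-rotated loadings.

    Observations are resampled with replacement; each bootstrap PCA +
    quartimax solution is aligned to the reference solution by maximal
    |Tucker congruence| column matching with sign correction before its
    loadings are accumulated. z = reference loading / bootstrap SD, with
    sd == 0 cells flagged undefined (NaN) rather than dropped.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if reference_model is None:
        reference_model = rotate_model(
            fit_pca(X, center=center, scale=scale, n_components=K)
        )
    ref = reference_model.loadings
    n = X.shape[0]
    acc = np.empty((n_boot, *ref.shape))
    n_resampled = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        if scale and (Xb.std(axis=0) == 0).any():
            n_resampled += 1
            continue
        model = rotate_model(fit_pca(Xb, center=center, scale=scale, n_components=K))
        perm, signs = match_components(ref, model.loadings)
        acc[b] = model.loadings[:, perm] * signs
        b += 1
    sd = acc.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(undefined, np.nan, ref / np.where(undefined, 1.0, sd))
    return BootstrapLoadings(
        loading_sd=sd, z=z, undefined=undefined, n_boot=n_boot, n_resampled=n_resampled
    )
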
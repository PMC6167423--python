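"""PCA outlier screening and the Kruskal-Wallis group test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..design import StudyDesign

__all__ = ["PCAScreenResult", "pca_screen", "kruskal_wallis"]


@dataclass(frozen=True)
class PCAScreenResult:
    scores: np.ndarray  # n x k
    loadings: np.ndarray  # p x k
    explained_variance_ratio: np.ndarray
    t2: np.ndarray  # Hotelling T^2 per sample over the retained components
    t2_critical: float
    outlier_flags: np.ndarray  # bool per sample


def pca_screen(X: np.ndarray, n_components: int, alpha: float = 0.05) -> PCAScreenResult:
    """PCA of a centered matrix with Hotelling-T2 outlier flagging.

    A sample is flagged when its T2 over the ``n_components`` retained
    components exceeds the F-distribution critical value
    ``k(n-1)/(n-k) * F_{k, n-k}(1-alpha)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA screening needs at least 3 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components
    # deterministic sign: largest-|.| loading entry positive
    for a in range(k):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    lam = s**2 / (n - 1)
    ratio = lam / lam.sum() if lam.sum() > 0 else lam
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(lam[:k] > 0, scores**2 / lam[:k], 0.0)
    t2 = terms.sum(axis=1)
    crit = k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)
    return PCAScreenResult(scores, loadings, ratio[:k], t2, float(crit), t2 > crit)


def kruskal_wallis(values: np.ndarray, design: StudyDesign) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p-value across the design's groups.

    Ties use average ranks with the standard tie correction.  All-equal
    values return (0, 1) rather than raising.  Rank-based, hence invariant
    under any strictly increasing transform of the values.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (design.n_samples,):
        raise ValueError("values must align with the design samples")
    labels = design.labels
    groups = [values[labels == g] for g in design.groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
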
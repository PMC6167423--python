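"""Orthogonal signal correction (OSC).

Removes from X the dominant structured variation that is orthogonal to
the treatment (the column-centered group dummy matrix Y), so that
confounding experimental or instrumental variation does not overshadow
the between-group variability the discriminant model is after.

Wold-style algorithm per removed component: seed the score with the first
principal-component score of X, orthogonalize it against Y, take the unit
weight vector solving the least-squares problem min ||Xw - t||, recompute
t = Xw, and iterate to convergence; a final orthogonalization enforces
the contract |corr(t, y)| ~ 0 exactly before X is deflated by t p' with
p = X't/(t't).  The input is always recoverable as filtered_X + sum t p'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..design import StudyDesign

__all__ = ["OSCResult", "osc_filter"]


@dataclass(frozen=True)
class OSCResult:
    """Outcome of OSC filtering.

    ``filtered_X + removed_scores @ removed_loadings.T`` reconstructs the
    input, and every removed score is numerically uncorrelated with every
    centered dummy column.
    """

    filtered_X: np.ndarray
    removed_scores: np.ndarray  # n x k
    removed_loadings: np.ndarray  # p x k
    variance_removed: np.ndarray  # fraction of total X sum-of-squares, per component
    iterations: tuple[int, ...]


def _project_out(Y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """t minus its projection onto the column space of Y (least squares,
    well-defined also for the rank-(g-1) centered dummy matrix)."""
    coef, *_ = np.linalg.lstsq(Y, t, rcond=None)
    return t - Y @ coef


def osc_filter(
    X: np.ndarray,
    design: StudyDesign,
    n_osc: int = 1,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> OSCResult:
    """Remove ``n_osc`` treatment-orthogonal components from centered X.

    Raises if the iteration has not converged within ``max_iter`` (the
    error carries the last relative score change) or if the design does
    not define at least two non-empty groups.
    """
    X = np.array(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if n_osc < 1:
        raise ValueError(f"n_osc must be >= 1, got {n_osc}")
    if X.shape[0] != design.n_samples:
        raise ValueError("X rows do not match the design")
    if len(design.groups) < 2:
        raise ValueError("OSC needs a design with at least 2 groups (Y rank-deficient)")
    Y, _ = design.indicator_matrix(center=True)

    total_ss = float((X**2).sum())
    if total_ss == 0:
        raise ValueError("X is identically zero")
    scores, loadings, var_removed, iters = [], [], [], []
    for _ in range(n_osc):
        # seed with the first PC score of the current X
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        t = X @ Vt[0]
        rel = np.inf
        converged = False
        for it in range(max_iter):
            t_orth = _project_out(Y, t)
            w, *_ = np.linalg.lstsq(X, t_orth, rcond=None)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("degenerate OSC weight (X exhausted)")
            w /= nw
            t_new = X @ w
            rel = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if rel < tol:
                converged = True
                break
        if not converged:
            raise ValueError(
                f"OSC did not converge in {max_iter} iterations "
                f"(last relative score change {rel:.3e}, tol {tol:.1e})"
            )
        t = _project_out(Y, t)  # enforce exact orthogonality to the response
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("OSC score vanished after orthogonalization")
        p = X.T @ t / tt
        removed = np.outer(t, p)
        X = X - removed
        scores.append(t)
        loadings.append(p)
        var_removed.append(float((removed**2).sum()) / total_ss)
        iters.append(it + 1)
    return OSCResult(
        X,
        np.column_stack(scores),
        np.column_stack(loadings),
        np.asarray(var_removed),
        tuple(iters),
    )
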
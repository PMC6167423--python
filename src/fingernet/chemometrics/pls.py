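"""NIPALS PLS-DA with cross-validated Q2, permutation validation and VIP.

The discriminant model regresses the (column-centered) group-indicator
dummy matrix Y on the spectral matrix X with the two-block NIPALS
algorithm (PLS2).  Model quality is summarized by R2Y, the fraction of
Y-variance explained in training, and Q2, the fraction predicted in
stratified k-fold cross-validation; the usual robustness rule of thumb in
metabolomic fingerprinting is R2Y > 50% and Q2 > 0.4.  Statistical
validity is assessed by refitting under random label permutations.

:class:`PLSDA` follows the model/results split: construct the model from
the data, call :meth:`PLSDA.fit`, and read estimates and diagnostics off
the returned :class:`PLSDAResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ..design import StudyDesign
from ..preprocess import SpectraMatrix

__all__ = [
    "PLSDA",
    "PLSDAResults",
    "PermutationResult",
    "VIPResult",
    "fit_plsda",
    "cross_validated_q2",
    "permutation_test",
    "vip_scores",
]

MAX_COMPONENTS = 10


# ----------------------------------------------------------------------
# core NIPALS
# ----------------------------------------------------------------------
def _nipals_pls2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-12,
    max_iter: int = 2000,
):
    """Two-block NIPALS on (X, Y); both are deflated on the X-scores.

    Returns (W, T, P, C, ssy) with unit-norm weight columns W, pairwise
    orthogonal score columns T, X-loadings P, Y-loadings C, and the
    Y sum-of-squares explained per component ssy[a] = (t't)(c'c).
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    n, p = X.shape
    g = Y.shape[1]
    A = n_components
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    C = np.zeros((g, A))
    ssy = np.zeros(A)
    x_scale = np.linalg.norm(X) or 1.0
    for a in range(A):
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
        if np.linalg.norm(u) < 1e-14 * x_scale:
            raise ValueError(
                f"Y exhausted after {a} components; cannot fit {A} "
                f"(attained rank {a})"
            )
        t = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(
                    f"X exhausted after {a} components (attained rank {a})"
                )
            w /= nw
            t_new = X @ w
            c = Y.T @ t_new / (t_new @ t_new)
            u = Y @ c / (c @ c)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt <= 1e-28 * x_scale**2:
            raise ValueError(f"degenerate score at component {a + 1} (attained rank {a})")
        # deterministic sign: largest-|.| weight entry positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w, t = -w, -t
        pl = X.T @ t / tt
        c = Y.T @ t / tt
        X = X - np.outer(t, pl)
        Y = Y - np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pl, c
        ssy[a] = tt * (c @ c)
    return W, T, P, C, ssy


def _regression_coefficients(W, P, C):
    """B such that Y_hat = X_centered @ B for the fitted components."""
    A = W.shape[1]
    M = P.T @ W  # upper triangular, unit diagonal
    R = W @ np.linalg.solve(M, np.eye(A))
    return R @ C.T


# ----------------------------------------------------------------------
# results containers
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class VIPResult:
    """Variable Importance in the Projection, one value per variable.

    VIP_j = sqrt( p * sum_a ssy_a (w_ja / ||w_a||)^2 / sum_a ssy_a );
    mean-square normalized so that sum_j VIP_j^2 = p.
    """

    vip: np.ndarray

    def __len__(self) -> int:
        return len(self.vip)


@dataclass(frozen=True)
class PermutationResult:
    """Observed vs label-permuted model statistics.

    ``empirical_p_q2 = (1 + #{permuted Q2 >= observed Q2}) / (n_perm + 1)``.
    """

    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    empirical_p_q2: float


@dataclass(frozen=True)
class PLSDAResults:
    """Estimates and diagnostics of a fitted PLS-DA model."""

    model: "PLSDA"
    n_components: int
    weights: np.ndarray  # W, p x A, unit-norm columns
    scores: np.ndarray  # T, n x A, pairwise orthogonal
    x_loadings: np.ndarray  # P, p x A
    y_loadings: np.ndarray  # C, g x A
    ssy_explained: np.ndarray  # per-component Y sum-of-squares explained
    r2y: float  # cumulative fraction, in [0, 1]
    r2y_per_component: np.ndarray
    q2: float | None  # cross-validated, cumulative at A
    q2_per_component: np.ndarray | None
    cv_folds: int | None
    seed: int | None

    # -- derived quantities -------------------------------------------
    def vip(self) -> VIPResult:
        return vip_scores(self)

    @property
    def coefficients(self) -> np.ndarray:
        return _regression_coefficients(self.weights, self.x_loadings, self.y_loadings)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted (centered-scale) dummy responses for new rows of X,
        which must be preprocessed like the training matrix."""
        return np.asarray(X_new, float) @ self.coefficients

    def permutation_test(self, n_perm: int = 200, seed: int = 0) -> PermutationResult:
        m = self.model
        return permutation_test(
            m.X, m.design, self.n_components, n_perm=n_perm, seed=seed,
            folds=self.cv_folds or 7,
        )

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "n_samples": int(self.scores.shape[0]),
            "n_variables": int(self.weights.shape[0]),
            "groups": list(self.model.design.groups),
            "r2y": float(self.r2y),
            "q2": None if self.q2 is None else float(self.q2),
        }

    def summary(self) -> str:
        m = self.model
        lines = [
            "PLS-DA results",
            "=" * 58,
            f"samples: {m.X.shape[0]}   variables: {m.X.shape[1]}   "
            f"groups: {len(m.design.groups)}",
            f"components: {self.n_components}",
            "",
            f"{'comp':>4} {'SSY explained':>14} {'R2Y(cum)':>10}"
            + (f" {'Q2(cum)':>10}" if self.q2 is not None else ""),
        ]
        r2cum = np.cumsum(self.r2y_per_component)
        q2cum = (
            None
            if self.q2_per_component is None
            else np.cumsum(np.asarray(self.q2_per_component))
        )
        for a in range(self.n_components):
            row = f"{a + 1:>4} {self.ssy_explained[a]:>14.4f} {r2cum[a]:>10.4f}"
            if q2cum is not None:
                row += f" {q2cum[a]:>10.4f}"
            lines.append(row)
        lines += [
            "-" * 58,
            f"R2Y = {self.r2y:.4f} ({100 * self.r2y:.1f}%)"
            + ("" if self.q2 is None else f"   Q2 = {self.q2:.4f}"),
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# the model object
# ----------------------------------------------------------------------
class PLSDA:
    """PLS discriminant analysis of a preprocessed spectral matrix.

    Parameters
    ----------
    X
        Preprocessed (centered, optionally Pareto-scaled) matrix,
        samples x variables.
    design
        Group assignment; at least two groups.  The response is the
        one-column-per-group dummy matrix, column-centered (standard PLS2
        discriminant coding, supporting any number of groups).
    """

    def __init__(self, X: np.ndarray, design: StudyDesign):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != design.n_samples:
            raise ValueError(
                f"X has {X.shape[0]} rows but the design has {design.n_samples} samples"
            )
        if len(design.groups) < 2:
            raise ValueError("PLS-DA needs at least 2 groups")
        self.X = X
        self.design = design
        self.Y, self.group_order = design.indicator_matrix(center=True)

    @classmethod
    def from_spectra(cls, m: SpectraMatrix, design: StudyDesign) -> "PLSDA":
        return cls(m.intensities, design)

    # ------------------------------------------------------------------
    def fit(
        self,
        n_components: int | None = None,
        max_components: int = MAX_COMPONENTS,
        cv_folds: int | None = 7,
        seed: int = 0,
    ) -> PLSDAResults:
        """Fit the model; returns a :class:`PLSDAResults`.

        If ``n_components`` is None the component count is chosen by
        cross-validation: components are added while the cumulative Q2
        increases, with a hard cap of ``max_components``.  With
        ``cv_folds=None`` no cross-validation is run (Q2 is None) and
        ``n_components`` must be given.
        """
        n, p = self.X.shape
        cap = min(max_components, n - 1, p)
        if n_components is not None:
            if not 1 <= n_components <= min(n - 1, p):
                raise ValueError(
                    f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
                )
            A = n_components
            q2cum = q2comp = None
            if cv_folds is not None:
                q2cum, q2comp = cross_validated_q2(
                    self.X, self.design, A, folds=cv_folds, seed=seed
                )
        else:
            if cv_folds is None:
                raise ValueError("either n_components or cv_folds must be given")
            q2cum, q2comp = cross_validated_q2(
                self.X, self.design, cap, folds=cv_folds, seed=seed
            )
            A = 1
            while A < cap and q2cum[A] > q2cum[A - 1]:
                A += 1
            q2cum, q2comp = q2cum[:A], q2comp[:A]

        W, T, P, C, ssy = _nipals_pls2(self.X, self.Y, A)
        ss_tot = float((self.Y**2).sum())
        r2_per = ssy / ss_tot
        return PLSDAResults(
            model=self,
            n_components=A,
            weights=W,
            scores=T,
            x_loadings=P,
            y_loadings=C,
            ssy_explained=ssy,
            r2y=float(r2_per.sum()),
            r2y_per_component=r2_per,
            q2=None if q2cum is None else float(q2cum[A - 1]),
            q2_per_component=None if q2comp is None else np.asarray(q2comp),
            cv_folds=cv_folds,
            seed=seed,
        )


# ----------------------------------------------------------------------
# functional surfaces
# ----------------------------------------------------------------------
def fit_plsda(
    X: np.ndarray, design: StudyDesign, n_components: int, **kwargs
) -> PLSDAResults:
    """Fit a PLS-DA model with a fixed component count."""
    return PLSDA(X, design).fit(n_components=n_components, **kwargs)


def cross_validated_q2(
    X: np.ndarray,
    design: StudyDesign,
    n_components: int,
    folds: int = 7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative and per-component Q2 by stratified k-fold CV.

    Q2(a) = 1 - PRESS(a)/SS, where PRESS sums squared errors of held-out
    dummy predictions using the first a components, and SS is the
    held-out sum of squares around the training group frequencies.
    Training X and Y are re-centered per fold with training means.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds the {n} samples")
    Y_raw, _ = design.indicator_matrix(center=False)
    labels = design.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = np.zeros(n_components)
    ss = 0.0
    for train, test in skf.split(X, labels):
        x_mean = X[train].mean(axis=0)
        y_mean = Y_raw[train].mean(axis=0)
        Xtr, Ytr = X[train] - x_mean, Y_raw[train] - y_mean
        Xte, Yte = X[test] - x_mean, Y_raw[test] - y_mean
        W, T, P, C, _ = _nipals_pls2(Xtr, Ytr, n_components)
        M = P.T @ W
        T_new = Xte @ (W @ np.linalg.solve(M, np.eye(n_components)))
        ss += float((Yte**2).sum())
        Y_hat = np.zeros_like(Yte)
        for a in range(n_components):
            Y_hat = Y_hat + np.outer(T_new[:, a], C[:, a])
            press[a] += float(((Yte - Y_hat) ** 2).sum())
    q2_cum = 1.0 - press / ss
    q2_per = np.empty(n_components)
    q2_per[0] = q2_cum[0]
    q2_per[1:] = (press[:-1] - press[1:]) / ss
    return q2_cum, q2_per


def permutation_test(
    X: np.ndarray,
    design: StudyDesign,
    n_components: int,
    n_perm: int = 200,
    seed: int = 0,
    folds: int = 7,
) -> PermutationResult:
    """Label-permutation validation of a PLS-DA model.

    Group labels are permuted uniformly at random ``n_perm`` times; R2Y
    and Q2 are recomputed per permutation with the same component count
    and fold count.  The attainable minimum of the empirical p-value is
    1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = PLSDA(X, design).fit(n_components=n_components, cv_folds=folds, seed=seed)
    obs_r2y, obs_q2 = res.r2y, res.q2
    rng = np.random.default_rng(seed)
    perm_r2 = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for k in range(n_perm):
        d_perm = design.permuted(rng)
        try:
            r = PLSDA(X, d_perm).fit(
                n_components=n_components, cv_folds=folds, seed=seed
            )
        except ValueError as exc:
            raise ValueError(f"permutation {k} failed: {exc}") from exc
        perm_r2[k] = r.r2y
        perm_q2[k] = r.q2
    p = (1 + int(np.sum(perm_q2 >= obs_q2))) / (n_perm + 1)
    return PermutationResult(obs_r2y, obs_q2, perm_r2, perm_q2, p)


def vip_scores(results: PLSDAResults) -> VIPResult:
    """VIP scores of a fitted model; sum of squared VIPs equals the
    number of variables."""
    if results.n_components < 1:
        raise ValueError("model has no components")
    ssy = np.asarray(results.ssy_explained, float)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained Y sum-of-squares; VIP undefined")
    W = results.weights
    norms = np.linalg.norm(W, axis=0)
    Wn = W / np.where(norms > 0, norms, 1.0)
    p = W.shape[0]
    vip = np.sqrt(p * (Wn**2 @ ssy) / total)
    return VIPResult(vip)
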
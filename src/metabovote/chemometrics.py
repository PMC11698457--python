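"""Projection models (NIPALS PCA/PLS, OPLS) with VIP and top-k feature selection.

This is branch A of the pipeline: fit a suite of latent-variable projections
of the UV-scaled feature matrix onto one or two activity targets (or onto
the active/non-active class indicators for the discriminant variants), keep
the models that survive the validity gate, and from each valid model select
the 25 features most aligned with activity on the first predictive
component, subject to VIP > 1.

All estimators operate on matrices that are already UV-scaled (X and Y);
scaling is a separate, inspectable preprocessing step (`data_model.uv_scale`).
Scores, weights and loadings follow the usual chemometrics notation:
T = scores, W = x-weights, P = x-loadings, C = y-loadings, with NIPALS
deflation X <- X - t p', Y <- Y - t c' per component.

VIP (variable importance for projection) for feature j over predictive
components a with explained-Y sums of squares SSY_a:

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

normalised so that the mean of VIP^2 over features is exactly 1.

Q2 is the cross-validated predictive fraction 1 - PRESS/SS_Y with SS_Y the
mean-centred total Y sum of squares, cumulative over components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.utils.validation import check_is_fitted

from .data_model import ACTIVE, TARGET_NAMES

METHODS = ("PCA", "PLS", "OPLS", "PLS-DA", "OPLS-DA")


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: method plus response definition.

    For the DA variants the regression response is the UV-scaled pair of
    class-indicator columns; ``y_spec`` then names the continuous target(s)
    used only to orient the activity direction of the components.
    """

    model_id: str
    method: str
    y_spec: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "PCA" and self.y_spec:
            raise ValueError("PCA takes no response")
        for t in self.y_spec:
            if t not in TARGET_NAMES:
                raise ValueError(f"unknown target {t!r}")

    @property
    def is_da(self) -> bool:
        return self.method.endswith("-DA")

    @property
    def is_orthogonal(self) -> bool:
        return self.method.startswith("OPLS")

    @property
    def is_supervised(self) -> bool:
        return self.method != "PCA"


def build_model_suite() -> list[ModelSpec]:
    """The 25 standard configurations M1-M25 (method x response)."""
    rows = [
        ("M1", "PCA", ()),
        ("M2", "PLS", ("inv_agi",)),
        ("M3", "PLS", ("ic50_agi",)),
        ("M4", "PLS-DA", ("inv_agi",)),
        ("M5", "OPLS-DA", ("inv_agi",)),
        ("M6", "OPLS", ("inv_agi",)),
        ("M7", "PLS", ("inv_agi", "inv_dpph")),
        ("M8", "OPLS", ("inv_agi", "inv_dpph")),
        ("M9", "PLS-DA", ("ic50_agi",)),
        ("M10", "OPLS-DA", ("ic50_agi",)),
        ("M11", "OPLS", ("ic50_agi",)),
        ("M12", "PLS", ("ic50_agi", "ic50_dpph")),
        ("M13", "OPLS", ("ic50_agi", "ic50_dpph")),
        ("M14", "PLS-DA", ("inv_agi", "inv_dpph")),
        ("M15", "OPLS-DA", ("inv_agi", "inv_dpph")),
        ("M16", "PLS-DA", ("ic50_agi", "ic50_dpph")),
        ("M17", "OPLS-DA", ("ic50_agi", "ic50_dpph")),
        ("M18", "PLS", ("inv_dpph",)),
        ("M19", "PLS-DA", ("inv_dpph",)),
        ("M20", "OPLS", ("inv_dpph",)),
        ("M21", "OPLS-DA", ("inv_dpph",)),
        ("M22", "PLS", ("ic50_dpph",)),
        ("M23", "PLS-DA", ("ic50_dpph",)),
        ("M24", "OPLS", ("ic50_dpph",)),
        ("M25", "OPLS-DA", ("ic50_dpph",)),
    ]
    return [ModelSpec(m, meth, tuple(y)) for m, meth, y in rows]


def encode_da_targets(labels: list[str]) -> np.ndarray:
    """Two UV-scaled indicator columns (active, non-active) for DA models."""
    y = np.column_stack(
        [
            [1.0 if lab == ACTIVE else 0.0 for lab in labels],
            [0.0 if lab == ACTIVE else 1.0 for lab in labels],
        ]
    )
    sd = y.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("class labels are constant; DA response is undefined")
    return (y - y.mean(axis=0)) / sd


@dataclass
class CVConfig:
    """Cross-validation layout: 7 interleaved folds unless configured otherwise."""

    n_folds: int = 7
    assignment: str = "interleaved"  # or "seeded_random"
    seed: int = 0

    def folds(self, n: int) -> list[np.ndarray]:
        k = self.n_folds
        if not 2 <= k <= n:
            raise ValueError(f"need 2 <= n_folds <= n_samples, got {k} for n={n}")
        idx = np.arange(n)
        if self.assignment == "seeded_random":
            idx = np.random.default_rng(self.seed).permutation(n)
        elif self.assignment != "interleaved":
            raise ValueError(f"unknown assignment {self.assignment!r}")
        return [idx[f::k] for f in range(k)]


# -- NIPALS cores -------------------------------------------------------------


def _nipals_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
                tol: float = 1e-12, max_iter: int = 1000):
    """NIPALS PLS with deterministic initialisation (largest-variance y column)."""
    X = X.copy()
    Y = Y.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    for a in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if not np.any(np.abs(u) > 0):
            raise ValueError(
                f"requested {n_components} components but achievable rank is {a}"
            )
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(
                    f"requested {n_components} components but achievable rank is {a}"
                )
            w /= nw
            t = X @ w
            tt = t @ t
            if tt <= tol * max(1.0, (X * X).sum()):
                raise ValueError(
                    f"requested {n_components} components but achievable rank is {a}"
                )
            c = Y.T @ t / tt
            if m == 1:
                break
            u_new = Y @ c / (c @ c)
            if np.linalg.norm(t - t_old) <= 1e-10 * np.linalg.norm(t):
                u = u_new
                break
            t_old, u = t, u_new
        p_a = X.T @ t / tt
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_a, c, t
        ssy[a] = tt * (c @ c)
        X -= np.outer(t, p_a)
        Y -= np.outer(t, c)
    return W, P, C, T, ssy, Y  # Y is the residual


class NipalsPCA(BaseEstimator, TransformerMixin):
    """Principal component analysis by NIPALS on a pre-scaled matrix."""

    def __init__(self, n_components: int = 2, tol: float = 1e-14, max_iter: int = 2000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).copy()
        n, p = X.shape
        total_ss = (X * X).sum()
        P = np.zeros((p, self.n_components))
        T = np.zeros((n, self.n_components))
        r2x = np.zeros(self.n_components)
        for a in range(self.n_components):
            j = int(np.argmax(X.var(axis=0)))
            t = X[:, j].copy()
            if np.linalg.norm(t) == 0:
                raise ValueError(
                    f"requested {self.n_components} components but achievable rank is {a}"
                )
            for _ in range(self.max_iter):
                p_a = X.T @ t / (t @ t)
                p_a /= np.linalg.norm(p_a)
                t_new = X @ p_a
                if np.linalg.norm(t_new - t) <= self.tol * np.linalg.norm(t_new):
                    t = t_new
                    break
                t = t_new
            P[:, a], T[:, a] = p_a, t
            r2x[a] = (t @ t) / total_ss
            X -= np.outer(t, p_a)
        self.loadings_ = P
        self.scores_ = T
        self.r2x_per_component_ = r2x
        self.explained_variance_ = (T * T).sum(axis=0) / (n - 1)
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        return np.asarray(X, dtype=float) @ self.loadings_


class NipalsPLS(BaseEstimator, RegressorMixin):
    """PLS regression by NIPALS; X and Y are expected pre-scaled.

    Fitted attributes: ``x_weights_`` (W), ``x_loadings_`` (P), ``y_loadings_``
    (C), ``x_scores_`` (T), ``x_rotations_`` (R = W (P'W)^-1 so that
    T = X R), ``coef_``, ``r2y_``, ``ssy_per_component_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        W, P, C, T, ssy, Yres = _nipals_pls(X, Y, self.n_components)
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = C
        self.x_scores_ = T
        self.x_rotations_ = W @ np.linalg.pinv(P.T @ W)
        self.coef_ = self.x_rotations_ @ C.T
        self.ssy_per_component_ = ssy
        tot = (Y * Y).sum()
        self.r2y_ = 1.0 - (Yres * Yres).sum() / tot if tot > 0 else 0.0
        self.r2y_per_target_ = 1.0 - (Yres * Yres).sum(axis=0) / (Y * Y).sum(axis=0)
        self.n_targets_ = Y.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "x_rotations_")
        return np.asarray(X, dtype=float) @ self.x_rotations_

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Yhat = np.asarray(X, dtype=float) @ self.coef_
        return Yhat[:, 0] if self.n_targets_ == 1 else Yhat

    def predict_components(self, X) -> np.ndarray:
        """Predictions for every cumulative component count, shape (A, n, m)."""
        check_is_fitted(self, "coef_")
        T = self.transform(X)
        out = np.empty((self.n_components, X.shape[0], self.y_loadings_.shape[0]))
        acc = np.zeros((X.shape[0], self.y_loadings_.shape[0]))
        for a in range(self.n_components):
            acc = acc + np.outer(T[:, a], self.y_loadings_[:, a])
            out[a] = acc
        return out


class OPLS(BaseEstimator, RegressorMixin):
    """Orthogonal projections to latent structures.

    Splits X variation into a Y-predictive part and ``n_orth`` components
    orthogonal to Y, then fits a NIPALS PLS with ``n_components`` predictive
    components on the filtered matrix.  For a univariate response with one
    predictive component the fitted Y equals that of a plain PLS with
    ``1 + n_orth`` components (rotation equivalence).
    """

    def __init__(self, n_components: int = 1, n_orth: int = 1):
        self.n_components = n_components
        self.n_orth = n_orth

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float).copy()
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        cov = X.T @ Y
        Wy, _ = np.linalg.qr(cov)  # orthonormal basis of the Y-covarying subspace
        p = X.shape[1]
        W_o = np.zeros((p, self.n_orth))
        P_o = np.zeros((p, self.n_orth))
        T_o = np.zeros((X.shape[0], self.n_orth))
        for a in range(self.n_orth):
            W1, P1, _, _, _, _ = _nipals_pls(X, Y, 1)
            p1 = P1[:, 0]
            w_o = p1 - Wy @ (Wy.T @ p1)
            norm = np.linalg.norm(w_o)
            if norm <= 1e-12:
                raise ValueError(
                    f"requested {self.n_orth} orthogonal components but achievable is {a}"
                )
            w_o /= norm
            t_o = X @ w_o
            p_o = X.T @ t_o / (t_o @ t_o)
            X -= np.outer(t_o, p_o)
            W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
        self.orth_x_weights_ = W_o
        self.orth_x_loadings_ = P_o
        self.orth_x_scores_ = T_o
        self.pls_ = NipalsPLS(self.n_components).fit(X, Y)
        self.n_targets_ = self.pls_.n_targets_
        return self

    # predictive-part views used by VIP / selection / direction
    @property
    def x_weights_(self):
        return self.pls_.x_weights_

    @property
    def x_loadings_(self):
        return self.pls_.x_loadings_

    @property
    def y_loadings_(self):
        return self.pls_.y_loadings_

    @property
    def x_scores_(self):
        return self.pls_.x_scores_

    @property
    def ssy_per_component_(self):
        return self.pls_.ssy_per_component_

    @property
    def r2y_(self):
        return self.pls_.r2y_

    @property
    def r2y_per_target_(self):
        return self.pls_.r2y_per_target_

    def _filter(self, X):
        X = np.asarray(X, dtype=float).copy()
        for a in range(self.n_orth):
            t_o = X @ self.orth_x_weights_[:, a]
            X -= np.outer(t_o, self.orth_x_loadings_[:, a])
        return X

    def transform(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.transform(self._filter(X))

    def predict(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(self._filter(X))

    def predict_components(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict_components(self._filter(X))


def make_estimator(spec: ModelSpec, n_components: int, n_orth: int = 0):
    if spec.method == "PCA":
        return NipalsPCA(n_components=n_components)
    if spec.is_orthogonal:
        return OPLS(n_components=n_components, n_orth=max(1, n_orth))
    return NipalsPLS(n_components=n_components)


# -- cross-validated prediction -----------------------------------------------


def q2_curve(X: np.ndarray, Y: np.ndarray, estimator, cv: CVConfig) -> np.ndarray:
    """Cumulative Q2 per component count: 1 - PRESS_A / SS_Y.

    Each fold refits a clone of ``estimator`` on the remaining rows of the
    (already scaled) matrices; held-out predictions accumulate PRESS.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    A = estimator.get_params()["n_components"]
    press = np.zeros(A)
    for fold in cv.folds(X.shape[0]):
        if len(fold) < 1:
            raise ValueError("cross-validation fold with no samples")
        mask = np.ones(X.shape[0], bool)
        mask[fold] = False
        model = clone(estimator).fit(X[mask], Y[mask])
        preds = model.predict_components(X[fold])
        press += ((preds - Y[fold][None]) ** 2).sum(axis=(1, 2))
    ssy = ((Y - Y.mean(axis=0)) ** 2).sum()
    return 1.0 - press / ssy


def q2(X: np.ndarray, Y: np.ndarray, estimator, cv: CVConfig) -> float:
    """Cumulative Q2 at the estimator's full component count."""
    return float(q2_curve(X, Y, estimator, cv)[-1])


def q2_press(X: np.ndarray, Y: np.ndarray, estimator, cv: CVConfig) -> tuple[float, np.ndarray]:
    """Q2 plus the per-target PRESS vector at full component count (for CV-ANOVA)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    press = np.zeros(Y.shape[1])
    for fold in cv.folds(X.shape[0]):
        mask = np.ones(X.shape[0], bool)
        mask[fold] = False
        model = clone(estimator).fit(X[mask], Y[mask])
        pred = model.predict(X[fold])
        if pred.ndim == 1:
            pred = pred[:, None]
        press += ((pred - Y[fold]) ** 2).sum(axis=0)
    ssy = ((Y - Y.mean(axis=0)) ** 2).sum()
    return float(1.0 - press.sum() / ssy), press


def choose_components(
    X: np.ndarray,
    Y: np.ndarray,
    spec: ModelSpec,
    cv: CVConfig,
    max_components: int = 5,
    min_gain: float = 0.05,
) -> tuple[int, int]:
    """Add components while Q2 improves by more than ``min_gain`` (cap 5).

    The 0.05 entry threshold is deliberately conservative for 30-sample
    studies: a marginal extra component roughly doubles the fit quality a
    *shuffled* response can reach, which defeats the response-permutation
    check downstream while adding almost no genuine predictive power.

    Returns (n_predictive, n_orthogonal).  OPLS keeps one predictive
    component per response column and grows the orthogonal part instead.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if spec.is_orthogonal:
        # one predictive component per independent response direction: the
        # two-class indicator pair is rank 1, so it gets one, not two
        n_pred = int(np.linalg.matrix_rank(Y - Y.mean(axis=0), tol=1e-8))
        n_pred = max(1, min(n_pred, Y.shape[1]))
        best = q2(X, Y, OPLS(n_components=n_pred, n_orth=1), cv)
        n_orth = 1
        for a in range(2, max_components + 1):
            try:
                cand = q2(X, Y, OPLS(n_components=n_pred, n_orth=a), cv)
            except ValueError:
                break
            if cand > best + min_gain:
                best, n_orth = cand, a
            else:
                break
        return n_pred, n_orth
    curve = q2_curve(X, Y, NipalsPLS(n_components=max_components), cv)
    n_pred = 1
    for a in range(1, max_components):
        if curve[a] > curve[n_pred - 1] + min_gain:
            n_pred = a + 1
        else:
            break
    return n_pred, 0


# -- importance and selection -------------------------------------------------


def vip(model) -> np.ndarray:
    """Variable importance for projection over the predictive components."""
    if isinstance(model, NipalsPCA):
        raise ValueError("VIP is defined for supervised models only")
    W = model.x_weights_
    ssy = model.ssy_per_component_
    if ssy.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


def activity_direction(model, target: np.ndarray) -> np.ndarray:
    """Sign of the correlation of each predictive score with the activity target."""
    T = model.x_scores_
    target = np.asarray(target, dtype=float)
    signs = np.empty(T.shape[1])
    for a in range(T.shape[1]):
        t = T[:, a]
        if t.std() == 0 or target.std() == 0:
            raise ValueError(f"zero-variance score or target for component {a + 1}")
        signs[a] = np.sign(np.corrcoef(t, target)[0, 1])
    return signs


def select_top_features(
    model,
    target: np.ndarray,
    var_ids: list[str],
    k: int = 25,
    vip_min: float = 1.0,
) -> list[str]:
    """Top-k features by activity-aligned loading on the first predictive
    component, restricted to VIP > ``vip_min``.

    Ranking is by s1 * p_j1 descending, where s1 orients the first component
    towards increasing activity, so a model whose activity direction is
    negative selects the most negative loadings — the convention used when
    reading loading plots by eye.  Ties keep stable (file) feature order.
    """
    s1 = activity_direction(model, target)[0]
    load = model.x_loadings_[:, 0]
    v = vip(model)
    scores = s1 * load
    order = np.argsort(-scores, kind="stable")
    picked = [var_ids[j] for j in order if v[j] > vip_min]
    return picked[:k]
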
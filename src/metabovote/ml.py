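"""Branch B: regression-model suite, bootstrap augmentation, and importances.

The suite predicts 1/IC50 AGI from the raw feature responses with five
regressors (linear regression as baseline plus four tree-based methods) at
fixed study settings, compares them by train/test RMSE and R2, and then
analyses the winning random forest (with and without stratified bootstrap
augmentation) with three importance readouts:

* permutation importance — mean RMSE increase over 100 shuffles per feature;
* SHAP score — mean |Shapley value| per feature (exact tree algorithm);
* correlation ranking — Pearson correlation of each raw feature with the
  target, most positive first.

Importance lists are capped at 25 entries and sign-screened: any listed
feature whose raw correlation with the target is not positive is removed,
because a feature that suppresses activity can dominate an importance
ranking yet cannot be a bioactive candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.tree import DecisionTreeRegressor

from . import shapley

ML_METHODS = (
    "linear_regression",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "ada_boost",
)


class PurityStoppedTreeRegressor(BaseEstimator, RegressorMixin):
    """Binary regression tree with an impurity-based early stop.

    "Node purity >= 95 %" is a classification notion; applied to regression
    it is read as: stop predicting deeper once a node's variance has fallen
    to <= (1 - purity) of the root variance.  Implemented as a prediction
    walk over a fitted sklearn tree that halts at the first such node, which
    is equivalent to not splitting it.
    """

    def __init__(
        self,
        min_samples_leaf: int = 2,
        min_samples_split: int = 5,
        purity: float = 0.95,
        random_state: int | None = None,
    ):
        self.min_samples_leaf = min_samples_leaf
        self.min_samples_split = min_samples_split
        self.purity = purity
        self.random_state = random_state

    def fit(self, X, y):
        self.tree_model_ = DecisionTreeRegressor(
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            random_state=self.random_state,
        ).fit(X, y)
        t = self.tree_model_.tree_
        self.impurity_stop_ = (1.0 - self.purity) * t.impurity[0]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        t = self.tree_model_.tree_
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = 0
            while t.children_left[node] != -1 and t.impurity[node] > self.impurity_stop_:
                if row[t.feature[node]] <= t.threshold[node]:
                    node = t.children_left[node]
                else:
                    node = t.children_right[node]
            out[i] = t.value[node].ravel()[0]
        return out


@dataclass
class MLConfig:
    """One regressor at the study's fixed hyperparameters."""

    method: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ML_METHODS:
            raise ValueError(f"unknown ML method {self.method!r}")

    def build(self):
        m, s = self.method, self.seed
        if m == "linear_regression":
            est = LinearRegression()
        elif m == "decision_tree":
            est = PurityStoppedTreeRegressor(
                min_samples_leaf=2, min_samples_split=5, purity=0.95, random_state=s
            )
        elif m == "random_forest":
            est = RandomForestRegressor(
                n_estimators=100, min_samples_split=2, random_state=s
            )
        elif m == "gradient_boosting":
            est = GradientBoostingRegressor(
                n_estimators=100,
                max_depth=3,
                min_samples_split=2,
                learning_rate=0.05,
                random_state=s,
            )
        else:  # ada_boost: 100 stumps, linear loss, learning rate 0.01
            est = AdaBoostRegressor(
                estimator=DecisionTreeRegressor(max_depth=1),
                n_estimators=100,
                loss="linear",
                learning_rate=0.01,
                random_state=s,
            )
        if self.overrides:
            est.set_params(**self.overrides)
        return est


@dataclass
class SplitConfig:
    train_fraction: float = 0.5
    seed: int = 0
    order: str = "split_then_augment"  # or "augment_then_split"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.order not in ("split_then_augment", "augment_then_split"):
            raise ValueError(f"unknown order {self.order!r}")


@dataclass
class PerformanceReport:
    method: str
    rmse_train: float
    r2_train: float
    rmse_test: float
    r2_test: float


@dataclass
class ImportanceList:
    """Ranked (var_id, score) pairs from one importance analysis."""

    method_tag: str
    entries: list[tuple[str, float]]

    @property
    def var_ids(self) -> list[str]:
        return [v for v, _ in self.entries]


# -- resampling ---------------------------------------------------------------


def bootstrap_indices(
    strata: np.ndarray, n_out: int = 50, seed: int | None = None
) -> np.ndarray:
    """Stratified bootstrap row indices: n_out draws with replacement, stratum
    proportions preserved up to largest-remainder rounding."""
    strata = np.asarray(strata)
    n = len(strata)
    if n == 0:
        raise ValueError("cannot bootstrap an empty dataset")
    rng = np.random.default_rng(seed)
    groups = pd.unique(strata)
    counts = np.array([(strata == g).sum() for g in groups])
    if (counts == 0).any():
        raise ValueError("empty stratum")
    exact = counts / n * n_out
    alloc = np.floor(exact).astype(int)
    rem = exact - alloc
    for g in np.argsort(-rem)[: n_out - alloc.sum()]:
        alloc[g] += 1
    out = []
    for g, k in zip(groups, alloc):
        pool = np.flatnonzero(strata == g)
        out.append(rng.choice(pool, size=k, replace=True))
    return np.concatenate(out)


def bootstrap_augment(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    n_out: int = 50,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified bootstrap of (X, y); returns (X_aug, y_aug, provenance indices)."""
    idx = bootstrap_indices(strata, n_out=n_out, seed=seed)
    return np.asarray(X)[idx], np.asarray(y)[idx], idx


def train_test_rows(n: int, split: SplitConfig, strata: np.ndarray | None = None):
    """Random 50/50 (by default) row split; stratified when labels are given."""
    rng = np.random.default_rng(split.seed)
    if strata is None:
        perm = rng.permutation(n)
        k = int(round(split.train_fraction * n))
        return perm[:k], perm[k:]
    train, test = [], []
    for g in pd.unique(np.asarray(strata)):
        pool = rng.permutation(np.flatnonzero(strata == g))
        k = int(round(split.train_fraction * len(pool)))
        train.append(pool[:k])
        test.append(pool[k:])
    return np.concatenate(train), np.concatenate(test)


def fit_and_evaluate(
    config: MLConfig,
    split: SplitConfig,
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray | None = None,
    augment_to: int | None = None,
) -> tuple[PerformanceReport, object, dict]:
    """Fit one regressor on a random split and report train/test RMSE and R2.

    With ``augment_to`` set, the data are bootstrap-augmented to that many
    rows.  Default order splits first and augments each side separately so no
    test row shares provenance with a training row; ``augment_then_split``
    reproduces the leakier convention of augmenting the pooled data first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    prov_train: np.ndarray
    if augment_to is not None and split.order == "augment_then_split":
        strata_full = strata if strata is not None else np.zeros(n, dtype=int)
        Xa, ya, idx = bootstrap_augment(X, y, strata_full, n_out=augment_to, seed=split.seed)
        tr, te = train_test_rows(len(ya), split, np.asarray(strata_full)[idx])
        Xtr, ytr, Xte, yte = Xa[tr], ya[tr], Xa[te], ya[te]
        prov_train, prov_test = idx[tr], idx[te]
    else:
        tr, te = train_test_rows(n, split, strata)
        Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
        prov_train, prov_test = tr, te
        if augment_to is not None:
            strata_full = strata if strata is not None else np.zeros(n, dtype=int)
            k_tr = int(round(split.train_fraction * augment_to))
            Xtr, ytr, i1 = bootstrap_augment(
                Xtr, ytr, np.asarray(strata_full)[tr], n_out=k_tr, seed=split.seed
            )
            Xte, yte, i2 = bootstrap_augment(
                Xte, yte, np.asarray(strata_full)[te], n_out=augment_to - k_tr, seed=split.seed + 1
            )
            prov_train, prov_test = tr[i1], te[i2]
    if len(ytr) == 0 or len(yte) == 0:
        raise ValueError("degenerate split: one side is empty")
    model = config.build().fit(Xtr, ytr)
    pred_tr, pred_te = model.predict(Xtr), model.predict(Xte)
    report = PerformanceReport(
        method=config.method,
        rmse_train=float(np.sqrt(mean_squared_error(ytr, pred_tr))),
        r2_train=float(r2_score(ytr, pred_tr)),
        rmse_test=float(np.sqrt(mean_squared_error(yte, pred_te))),
        r2_test=float(r2_score(yte, pred_te)),
    )
    data = {
        "X_train": Xtr, "y_train": ytr, "X_test": Xte, "y_test": yte,
        "prov_train": prov_train, "prov_test": prov_test,
    }
    return report, model, data


def compare_methods(
    X: np.ndarray,
    y: np.ndarray,
    split: SplitConfig,
    strata: np.ndarray | None = None,
    augment_to: int | None = None,
    seed: int = 0,
    methods: tuple[str, ...] = ML_METHODS,
) -> pd.DataFrame:
    """Performance table (RMSE/R2, train and test) across the method suite."""
    rows = []
    for m in methods:
        rep, _, _ = fit_and_evaluate(MLConfig(m, seed=seed), split, X, y, strata, augment_to)
        rows.append(vars(rep))
    return pd.DataFrame(rows)


# -- importances --------------------------------------------------------------


def permutation_importance(
    model, X: np.ndarray, y: np.ndarray, n_perm: int = 100, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean RMSE increase (and sd) per feature over ``n_perm`` shuffles.

    Equivalent to scoring each shuffle separately (score_j = mean over
    shuffles of RMSE_permuted - RMSE_baseline) but batches the ``n_perm``
    shuffled copies of a feature into one prediction call, which matters when
    the model is a 100-tree forest queried 80 x 100 times.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    baseline = float(np.sqrt(mean_squared_error(y, model.predict(X))))
    mean_delta = np.empty(p)
    sd_delta = np.empty(p)
    for j in range(p):
        stacked = np.tile(X, (n_perm, 1))
        for r in range(n_perm):
            stacked[r * n : (r + 1) * n, j] = X[rng.permutation(n), j]
        pred = model.predict(stacked).reshape(n_perm, n)
        rmses = np.sqrt(((pred - y[None, :]) ** 2).mean(axis=1))
        mean_delta[j] = rmses.mean() - baseline
        sd_delta[j] = rmses.std()
    return mean_delta, sd_delta


def importance_list(
    scores: np.ndarray, var_ids: list[str], method_tag: str, k: int = 25
) -> ImportanceList:
    order = np.argsort(-scores, kind="stable")[:k]
    return ImportanceList(method_tag, [(var_ids[j], float(scores[j])) for j in order])


def correlation_ranking(
    X_raw: np.ndarray, target: np.ndarray, var_ids: list[str], k: int = 25
) -> tuple[ImportanceList, pd.Series]:
    """Pearson correlation of each raw feature with the target; top-k most positive."""
    X_raw = np.asarray(X_raw, dtype=float)
    target = np.asarray(target, dtype=float)
    if target.std(ddof=1) == 0:
        raise ValueError("target is constant; correlations undefined")
    xc = X_raw - X_raw.mean(axis=0)
    tc = target - target.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ tc / denom, 0.0)
    series = pd.Series(r, index=var_ids)
    return importance_list(r, var_ids, "correlation", k), series


def sign_screen(lst: ImportanceList, correlations: pd.Series) -> ImportanceList:
    """Drop listed features whose correlation with the target is not positive."""
    missing = [v for v, _ in lst.entries if v not in correlations.index]
    if missing:
        raise KeyError(f"no correlation value for features {missing}")
    kept = [(v, s) for v, s in lst.entries if correlations[v] > 0]
    return ImportanceList(lst.method_tag, kept)


def rf_importance_lists(
    X: np.ndarray,
    y: np.ndarray,
    var_ids: list[str],
    strata: np.ndarray | None = None,
    n_perm: int = 100,
    k: int = 25,
    augment_to: int = 50,
    seed: int = 0,
) -> list[ImportanceList]:
    """The four random-forest lists: permutation and SHAP, with/without bootstrap.

    Importances are evaluated on the full (possibly augmented) dataset the
    forest was trained on, which is also the SHAP background set.
    """
    out = []
    for boot in (False, True):
        if boot:
            strata_full = strata if strata is not None else np.zeros(len(y), dtype=int)
            Xb, yb, _ = bootstrap_augment(X, y, strata_full, n_out=augment_to, seed=seed)
        else:
            Xb, yb = np.asarray(X, dtype=float), np.asarray(y, dtype=float)
        rf = MLConfig("random_forest", seed=seed).build().fit(Xb, yb)
        tag = "_boot" if boot else ""
        mean_d, _ = permutation_importance(rf, Xb, yb, n_perm=n_perm, seed=seed)
        out.append(importance_list(mean_d, var_ids, f"perm_rf{tag}", k))
        out.append(importance_list(shapley.shap_scores(rf, Xb), var_ids, f"shap_rf{tag}", k))
    return out
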
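"""Three-criterion model-validity gate for the projection-model suite.

A supervised projection model is kept only if it passes all of:

1. overfit gap: R2Y - Q2 <= 0.3;
2. response permutation: refit the model on row-shuffled responses (X
   untouched) 20 times; regress the permuted R2Y and Q2 against the
   |correlation| of the shuffled response to the original, including the
   unpermuted point at correlation 1; the R2 line's intercept at
   correlation 0 must be <= 0.4 and the Q2 line's <= 0.05;
3. CV-ANOVA: an F-test of the cross-validated predictive residuals against
   the mean-only model, per response column, p <= 0.05.

The permutation intercepts estimate what fit quality a comparable but
information-free response would achieve; a well-determined model sits far
above its own permuted cloud and has a negative Q2 intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone

from .chemometrics import (
    CVConfig,
    ModelSpec,
    choose_components,
    make_estimator,
    q2_press,
)

#: gate thresholds: overfit gap, R2 intercept, Q2 intercept, CV-ANOVA p
DEFAULT_THRESHOLDS = {"diff": 0.3, "r2_intercept": 0.4, "q2_intercept": 0.05, "p": 0.05}


@dataclass(frozen=True)
class PermutationRun:
    correlation: float  # |corr| of the shuffled response to the original
    r2y_perm: float
    q2_perm: float


@dataclass
class ValidityReport:
    model_id: str
    r2y: float
    q2: float
    r2_intercept: float
    q2_intercept: float
    cvanova_p: list[float]
    n_components: int = 0
    n_orth: int = 0
    valid: bool = field(init=False)

    @property
    def diff(self) -> float:
        return self.r2y - self.q2

    def __post_init__(self) -> None:
        self.valid = is_valid(
            self.diff, self.r2_intercept, self.q2_intercept, self.cvanova_p
        )


def is_valid(
    diff: float,
    r2_intercept: float,
    q2_intercept: float,
    pvals: list[float] | None,
    thresholds: dict[str, float] = DEFAULT_THRESHOLDS,
) -> bool:
    ok = (
        diff <= thresholds["diff"]
        and r2_intercept <= thresholds["r2_intercept"]
        and q2_intercept <= thresholds["q2_intercept"]
    )
    if pvals:
        ok = ok and max(pvals) <= thresholds["p"]
    return ok


def _fit_stats(X, Y, estimator, cv: CVConfig) -> tuple[float, float]:
    est = clone(estimator)  # never clobber the caller's fitted model
    model = est.fit(X, Y)
    q2_val, _ = q2_press(X, Y, est, cv)
    return float(model.r2y_), q2_val


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    estimator,
    cv: CVConfig,
    n_perm: int = 20,
    seed: int | None = None,
    include_original: bool = True,
) -> tuple[list[PermutationRun], float, float]:
    """Response-permutation test; returns runs and the two regression intercepts.

    Whole Y rows are shuffled so multi-target responses stay paired; X is
    left bit-identical.  The unpermuted model anchors the regression at
    correlation 1 (the usual plotting convention), configurable off.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    r2y0, q20 = _fit_stats(X, Y2, estimator, cv)
    runs: list[PermutationRun] = []
    for _ in range(n_perm):
        perm = rng.permutation(Y2.shape[0])
        Yp = Y2[perm]
        cors = [
            abs(np.corrcoef(Yp[:, j], Y2[:, j])[0, 1]) for j in range(Y2.shape[1])
        ]
        r2p, q2p = _fit_stats(X, Yp, estimator, cv)
        runs.append(PermutationRun(float(np.mean(cors)), r2p, q2p))
    xs = [r.correlation for r in runs]
    r2s = [r.r2y_perm for r in runs]
    q2s = [r.q2_perm for r in runs]
    if include_original:
        xs, r2s, q2s = xs + [1.0], r2s + [r2y0], q2s + [q20]
    r2_line = np.polyfit(xs, r2s, 1)
    q2_line = np.polyfit(xs, q2s, 1)
    return runs, float(r2_line[1]), float(q2_line[1])


def cv_anova(
    press: float, ss_total: float, n_samples: int, n_components: int
) -> float:
    """Upper-tail p of the CV-ANOVA F statistic.

    F = ((SS - PRESS)/A) / (PRESS/(N-1-A)) with A model components; a model
    no better than the response mean (PRESS >= SS) gives F = 0, p = 1.
    """
    if not np.isfinite(press) or not np.isfinite(ss_total):
        raise ValueError("non-finite residual sums of squares")
    a = max(1, n_components)
    df2 = n_samples - 1 - a
    if df2 <= 0:
        raise ValueError("too few samples for CV-ANOVA degrees of freedom")
    if press <= 0:
        return 0.0
    f = max(0.0, (ss_total - press) / a) / (press / df2)
    return float(stats.f.sf(f, a, df2))


def evaluate_model(
    X: np.ndarray,
    Y: np.ndarray,
    spec: ModelSpec,
    cv: CVConfig,
    n_perm: int = 20,
    seed: int | None = None,
    thresholds: dict[str, float] = DEFAULT_THRESHOLDS,
) -> tuple[ValidityReport, object]:
    """Fit one supervised configuration and run the full gate on it."""
    if not spec.is_supervised:
        raise ValueError("the validity gate applies to supervised models only")
    Y = np.asarray(Y, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    n_pred, n_orth = choose_components(X, Y2, spec, cv)
    estimator = make_estimator(spec, n_pred, n_orth)
    model = estimator.fit(X, Y2)
    q2_val, press = q2_press(X, Y2, estimator, cv)
    _, r2_int, q2_int = permutation_test(X, Y2, estimator, cv, n_perm=n_perm, seed=seed)
    n = X.shape[0]
    a_total = n_pred + n_orth
    ss_cols = ((Y2 - Y2.mean(axis=0)) ** 2).sum(axis=0)
    pvals = [cv_anova(float(press[j]), float(ss_cols[j]), n, a_total) for j in range(Y2.shape[1])]
    report = ValidityReport(
        model_id=spec.model_id,
        r2y=float(model.r2y_),
        q2=q2_val,
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        cvanova_p=pvals,
        n_components=n_pred,
        n_orth=n_orth,
    )
    report.valid = is_valid(report.diff, r2_int, q2_int, pvals, thresholds)
    return report, model


def gate(
    specs: list[ModelSpec],
    X: np.ndarray,
    targets: dict[str, np.ndarray],
    da_response: np.ndarray,
    cv: CVConfig,
    seed: int | None = None,
    n_perm: int = 20,
    thresholds: dict[str, float] = DEFAULT_THRESHOLDS,
) -> tuple[list[ValidityReport], dict[str, object]]:
    """Run the gate over a model suite; PCA entries carry no response and are skipped.

    ``targets`` maps target names to vectors; ``da_response`` is the UV-scaled
    class-indicator matrix used as the regression response of DA models.
    Returns the reports plus the fitted models keyed by model_id.
    """
    reports: list[ValidityReport] = []
    models: dict[str, object] = {}
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seeds = ss.generate_state(len(specs))
    for spec, s in zip(specs, seeds):
        if not spec.is_supervised:
            continue
        if spec.is_da:
            Y = da_response
        else:
            Y = np.column_stack([targets[t] for t in spec.y_spec])
            Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
        report, model = evaluate_model(
            X, Y, spec, cv, n_perm=n_perm, seed=int(s), thresholds=thresholds
        )
        reports.append(report)
        models[spec.model_id] = model
    return reports, models
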
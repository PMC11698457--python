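"""Core containers and preprocessing for LC-MS feature tables and bioassay activities.

The pipeline consumes a sample x feature table of nonnegative LC-MS peak
responses (a response of 0 means the ion was not detected in that extract)
together with per-sample IC50 values from two bioassays: alpha-glucosidase
inhibition (AGI) and the DPPH radical-scavenging antioxidant assay.  IC50
decreases with potency, so the regression targets are the reciprocals
1/IC50, which increase with activity.

Scaling follows the unit-variance (UV) autoscaling convention of
chemometrics: every feature is centred to mean 0 and divided by its sample
standard deviation (n-1 denominator).  Zero-variance features carry no
information for any projection model and are dropped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

ACTIVE = "active"
NON_ACTIVE = "non_active"

#: Targets understood by supervised models, in canonical order.
TARGET_NAMES = ("inv_agi", "ic50_agi", "inv_dpph", "ic50_dpph")


@dataclass(frozen=True)
class SampleMeta:
    """Identity and extraction condition of one extract sample."""

    sample_id: str
    ethanol_pct: float  # percent ethanol in the extraction solvent, 0..100
    replicate: int

    def __post_init__(self) -> None:
        if not 0.0 <= float(self.ethanol_pct) <= 100.0:
            raise ValueError(
                f"ethanol_pct must lie in [0, 100], got {self.ethanol_pct} "
                f"for sample {self.sample_id!r}"
            )
        if int(self.replicate) < 1:
            raise ValueError(f"replicate must be positive for sample {self.sample_id!r}")


@dataclass(frozen=True)
class FeatureMeta:
    """One m/z feature: an ion signal whose response proxies a metabolite amount."""

    var_id: str
    mz: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"m/z must be positive, got {self.mz} for {self.var_id!r}")


class FeatureTable:
    """Sample x feature matrix of LC-MS peak responses with metadata.

    Feature order is file order and is never re-sorted: downstream consensus
    voting identifies features by ``var_id``, and stable identity matters more
    than any ordering convention.
    """

    def __init__(
        self,
        samples: list[SampleMeta],
        features: list[FeatureMeta],
        responses: np.ndarray,
    ) -> None:
        responses = np.asarray(responses, dtype=float)
        if responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if responses.shape != (len(samples), len(features)):
            raise ValueError(
                f"responses shape {responses.shape} does not match "
                f"{len(samples)} samples x {len(features)} features"
            )
        if np.isnan(responses).any():
            i, j = np.argwhere(np.isnan(responses))[0]
            raise ValueError(
                f"missing value at sample {samples[i].sample_id!r}, "
                f"feature {features[j].var_id!r}"
            )
        if (responses < 0).any():
            i, j = np.argwhere(responses < 0)[0]
            raise ValueError(
                f"negative response at sample {samples[i].sample_id!r}, "
                f"feature {features[j].var_id!r}"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = next(x for x in ids if ids.count(x) > 1)
            raise ValueError(f"duplicate sample_id {dup!r}")
        vids = [f.var_id for f in features]
        if len(set(vids)) != len(vids):
            dup = next(x for x in vids if vids.count(x) > 1)
            raise ValueError(f"duplicate var_id {dup!r}")
        self.samples = list(samples)
        self.features = list(features)
        self.responses = responses

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def var_ids(self) -> list[str]:
        return [f.var_id for f in self.features]

    @property
    def mz(self) -> np.ndarray:
        return np.array([f.mz for f in self.features])

    @property
    def ethanol_pct(self) -> np.ndarray:
        return np.array([s.ethanol_pct for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.var_ids)
        df.insert(0, "replicate", [s.replicate for s in self.samples])
        df.insert(0, "ethanol_pct", [s.ethanol_pct for s in self.samples])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"var_id": self.var_ids, "mz": self.mz})


@dataclass
class ActivityTable:
    """Per-sample IC50 values (ppm) and their reciprocals for both assays."""

    sample_id: list[str]
    ic50_agi: np.ndarray
    ic50_dpph: np.ndarray
    inv_agi: np.ndarray = field(default=None)  # type: ignore[assignment]
    inv_dpph: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ic50_agi = np.asarray(self.ic50_agi, dtype=float)
        self.ic50_dpph = np.asarray(self.ic50_dpph, dtype=float)
        if (self.ic50_agi <= 0).any() or (self.ic50_dpph <= 0).any():
            raise ValueError("IC50 values must be strictly positive")
        if self.inv_agi is None or self.inv_dpph is None:
            reciprocal_targets(self, inplace=True)
        else:
            self.inv_agi = np.asarray(self.inv_agi, dtype=float)
            self.inv_dpph = np.asarray(self.inv_dpph, dtype=float)

    def target(self, name: str) -> np.ndarray:
        """Return one of the four target vectors by canonical name."""
        if name not in TARGET_NAMES:
            raise KeyError(f"unknown target {name!r}; expected one of {TARGET_NAMES}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "ic50_agi": self.ic50_agi,
                "ic50_dpph": self.ic50_dpph,
                "inv_agi": self.inv_agi,
                "inv_dpph": self.inv_dpph,
            }
        )


@dataclass
class ScaledMatrix:
    """UV-scaled response matrix plus the statistics needed to invert it."""

    values: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    var_ids: list[str]
    dropped_features: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def unscale(self) -> np.ndarray:
        return self.values * self.col_sds + self.col_means


class UVScaler(BaseEstimator, TransformerMixin):
    """Unit-variance autoscaler (mean 0, sample sd 1 per column).

    Unlike ``sklearn.preprocessing.StandardScaler`` this uses the n-1
    standard deviation and *drops* zero-variance columns instead of leaving
    them at zero, reporting them in ``dropped_features_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("UV scaling needs a 2-D matrix with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.keep_mask_ = self.scale_ > 0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) / np.where(self.keep_mask_, self.scale_, 1.0))[
            :, self.keep_mask_
        ]


def uv_scale(table: FeatureTable | np.ndarray, var_ids: list[str] | None = None) -> ScaledMatrix:
    """UV-scale a feature table; zero-variance columns are dropped, not imputed."""
    if isinstance(table, FeatureTable):
        X = table.responses
        var_ids = table.var_ids
    else:
        X = np.asarray(table, dtype=float)
        if var_ids is None:
            var_ids = [f"Var{j + 1}" for j in range(X.shape[1])]
    scaler = UVScaler().fit(X)
    keep = scaler.keep_mask_
    dropped = [v for v, k in zip(var_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        logger.warning("dropping zero-variance features: %s", dropped)
    return ScaledMatrix(
        values=scaler.transform(X),
        col_means=scaler.mean_[keep],
        col_sds=scaler.scale_[keep],
        var_ids=[v for v, k in zip(var_ids, keep) if k],
        dropped_features=dropped,
    )


def reciprocal_targets(activity: ActivityTable, inplace: bool = False) -> ActivityTable:
    """Populate 1/IC50 targets so that stronger activity means a larger value."""
    if (activity.ic50_agi <= 0).any() or (activity.ic50_dpph <= 0).any():
        raise ValueError("IC50 values must be strictly positive")
    inv_agi = 1.0 / activity.ic50_agi
    inv_dpph = 1.0 / activity.ic50_dpph
    if inplace:
        activity.inv_agi = inv_agi
        activity.inv_dpph = inv_dpph
        return activity
    return ActivityTable(
        sample_id=list(activity.sample_id),
        ic50_agi=activity.ic50_agi.copy(),
        ic50_dpph=activity.ic50_dpph.copy(),
        inv_agi=inv_agi,
        inv_dpph=inv_dpph,
    )


def assign_classes(table: FeatureTable) -> list[str]:
    """Active class = the 100%-ethanol extracts; everything else is non-active.

    The split mirrors the observation that the pure-ethanol extracts have the
    highest 1/IC50 AGI values, and it defines the response for the
    discriminant-analysis (DA) model variants.
    """
    return [ACTIVE if s.ethanol_pct == 100 else NON_ACTIVE for s in table.samples]


# -- file I/O -----------------------------------------------------------------

_META_COLS = ("sample_id", "ethanol_pct", "replicate")


def load_feature_table(path: str | Path, feature_meta_path: str | Path | None = None) -> FeatureTable:
    """Read a feature-table CSV (``sample_id,ethanol_pct,replicate,<var_id>...``).

    m/z values come from a companion metadata CSV (``var_id,mz``) or from a
    ``var_id:mz`` header convention; without either, m/z defaults to NaN-free
    placeholder ordinals (merging by m/z then degenerates to identity).
    """
    df = pd.read_csv(path)
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"feature table is missing required column {col!r}")
    resp = df.drop(columns=list(_META_COLS))
    mz_map: dict[str, float] = {}
    if feature_meta_path is not None:
        meta = pd.read_csv(feature_meta_path)
        mz_map = dict(zip(meta["var_id"].astype(str), meta["mz"].astype(float)))
    cols: list[str] = []
    for c in resp.columns:
        if ":" in c:  # "var_id:mz" header convention
            vid, mz = c.rsplit(":", 1)
            mz_map[vid] = float(mz)
            cols.append(vid)
        else:
            cols.append(c)
    resp.columns = cols
    if resp.isna().any().any():
        j = resp.columns[resp.isna().any()][0]
        i = df.loc[resp[j].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing value at sample {i!r}, feature {j!r}")
    samples = [
        SampleMeta(str(r.sample_id), float(r.ethanol_pct), int(r.replicate))
        for r in df[list(_META_COLS)].itertuples(index=False)
    ]
    features = [FeatureMeta(v, mz_map.get(v, float(j + 1))) for j, v in enumerate(cols)]
    return FeatureTable(samples, features, resp.to_numpy(dtype=float))


def save_feature_table(table: FeatureTable, path: str | Path, decimals: int = 6) -> None:
    df = table.to_frame()
    num = df.columns.difference(_META_COLS)
    df[num] = df[num].round(decimals)
    df.to_csv(path, index=False)


def load_activity_table(path: str | Path) -> ActivityTable:
    df = pd.read_csv(path)
    for col in ("sample_id", "ic50_agi", "ic50_dpph"):
        if col not in df.columns:
            raise ValueError(f"activity table is missing required column {col!r}")
    return ActivityTable(
        sample_id=df["sample_id"].astype(str).tolist(),
        ic50_agi=df["ic50_agi"].to_numpy(dtype=float),
        ic50_dpph=df["ic50_dpph"].to_numpy(dtype=float),
    )


def save_activity_table(activity: ActivityTable, path: str | Path) -> None:
    activity.to_frame().to_csv(path, index=False)
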
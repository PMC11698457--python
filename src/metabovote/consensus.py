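"""Frequency voting, branch intersection, m/z merging and correlation analysis.

The two branches each produce several top-25 feature lists.  Within a
branch, features are kept when they appear in more than (statistical branch,
strict) or at least (ML branch, non-strict) 50 % of the lists.  The final
prediction is the intersection of the two branch selections; features whose
m/z agree within tolerance are merged into one predicted compound, since one
metabolite can be detected as several features.

The post-analysis computes the Pearson correlation matrix of the candidate
features (average-linkage clustering at distance 1 - r suggests compound
groups, possibly biosynthetically related) and the 4x4 cross-correlation of
the activity variables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_model import ActivityTable, TARGET_NAMES


def _var_key(var_id: str):
    """Sort features by the numeric part of their id, then lexically."""
    m = re.search(r"(\d+)$", var_id)
    return (0, int(m.group(1)), var_id) if m else (1, 0, var_id)


@dataclass
class VoteResult:
    """Per-feature appearance counts over a set of source lists."""

    counts: dict[str, int]
    n_lists: int
    threshold_pct: float
    strict: bool

    @property
    def appearance_pct(self) -> dict[str, float]:
        return {v: 100.0 * c / self.n_lists for v, c in self.counts.items()}

    @property
    def selected(self) -> set[str]:
        pct = self.appearance_pct
        if self.strict:
            return {v for v, p in pct.items() if p > self.threshold_pct}
        return {v for v, p in pct.items() if p >= self.threshold_pct}

    def to_frame(self) -> pd.DataFrame:
        pct = self.appearance_pct
        sel = self.selected
        rows = sorted(self.counts, key=_var_key)
        return pd.DataFrame(
            {
                "var_id": rows,
                "appearance_count": [self.counts[v] for v in rows],
                "appearance_pct": [pct[v] for v in rows],
                "selected": [v in sel for v in rows],
            }
        )


def vote(
    lists: list[list[str]], threshold_pct: float = 50.0, strict: bool = True
) -> VoteResult:
    """Count appearances of each feature over the source lists.

    ``strict`` selects at > threshold (statistical-branch wording);
    non-strict at >= threshold (ML-branch wording).
    """
    if not lists:
        raise ValueError("voting needs at least one source list")
    counts: dict[str, int] = {}
    for lst in lists:
        for v in set(lst):
            counts[v] = counts.get(v, 0) + 1
    return VoteResult(counts, len(lists), threshold_pct, strict)


def intersect(stat: set[str], ml_sel: set[str]) -> list[str]:
    """Features selected by both branches, in deterministic var-id order."""
    return sorted(set(stat) & set(ml_sel), key=_var_key)


def merge_by_mz(
    features: list[tuple[str, float]],
    tol_mode: str = "exact3dp",
    ppm_tol: float = 10.0,
) -> list[tuple[float, list[str]]]:
    """Merge features whose m/z agree under tolerance into predicted compounds.

    ``exact3dp`` merges on equality after rounding to 3 decimals (the
    precision at which the feature tables print m/z); ``ppm`` merges by
    single-linkage within a relative tolerance, for raw instrument values.
    Returns (representative m/z, member var_ids) per compound, ordered by m/z.
    """
    if tol_mode not in ("exact3dp", "ppm"):
        raise ValueError(f"unknown tol_mode {tol_mode!r}")
    items = sorted(features, key=lambda f: (f[1], _var_key(f[0])))
    groups: list[list[tuple[str, float]]] = []
    for vid, mz in items:
        if groups:
            _, last_mz = groups[-1][-1]
            if tol_mode == "exact3dp":
                same = round(mz, 3) == round(last_mz, 3)
            else:
                same = abs(mz - last_mz) / last_mz * 1e6 <= ppm_tol
            if same:
                groups[-1].append((vid, mz))
                continue
        groups.append([(vid, mz)])
    return [
        (float(np.mean([mz for _, mz in g])), sorted([v for v, _ in g], key=_var_key))
        for g in groups
    ]


def correlation_matrix(X_raw: np.ndarray, var_ids: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix of the given features (raw responses)."""
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = X_raw.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = var_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance feature {bad!r}: correlation undefined")
    r = np.corrcoef(X_raw, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=var_ids, columns=var_ids)


def group_features(corr: pd.DataFrame, cut: float = 0.5) -> list[set[str]]:
    """Average-linkage clusters of features at distance 1 - r, cut at ``cut``.

    A reproducible stand-in for grouping a correlation heat map by eye.
    """
    if corr.shape[0] == 1:
        return [set(corr.index)]
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    labels = fcluster(linkage(squareform(d, checks=False), method="average"), t=cut, criterion="distance")
    out: dict[int, set[str]] = {}
    for v, lab in zip(corr.index, labels):
        out.setdefault(int(lab), set()).add(v)
    return [out[k] for k in sorted(out)]


def activity_cross_correlation(activity: ActivityTable) -> pd.DataFrame:
    """4x4 Pearson matrix over {1/IC50 AGI, IC50 AGI, 1/IC50 DPPH, IC50 DPPH}."""
    cols = {name: activity.target(name) for name in TARGET_NAMES}
    n = len(next(iter(cols.values())))
    if n < 3:
        raise ValueError("need at least 3 samples")
    for name, v in cols.items():
        if np.std(v, ddof=1) == 0:
            raise ValueError(f"activity column {name!r} is constant")
    mat = np.corrcoef(np.column_stack(list(cols.values())), rowvar=False)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=list(TARGET_NAMES), columns=list(TARGET_NAMES))
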
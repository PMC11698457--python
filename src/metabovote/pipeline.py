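"""End-to-end orchestration: both branches, the consensus, and the reports.

``run_all`` executes the whole procedure on a feature table + activity table
(loaded from CSV or drawn from the synthetic generator):

1. UV-scale the responses; derive 1/IC50 targets and the active/non-active
   class split (100 % ethanol extracts = active).
2. Branch A: fit the 25-model projection suite, apply the three-criterion
   validity gate, select the top-25 activity-aligned features (VIP > 1) from
   every valid model, and vote (strict > 50 %).
3. Branch B: compare the regression suite, then take the four random-forest
   importance lists (permutation / SHAP, with and without bootstrap
   augmentation) plus the correlation top-25, sign-screen each against the
   target correlations, and vote (non-strict >= 50 %).
4. Intersect the branch selections, merge features by m/z into predicted
   compounds, and run the correlation post-analyses.

Every stochastic stage derives its own seed from one pipeline seed, and a
run manifest (config echo, seeds, input checksums) makes deterministic
stages reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import ml
from .chemometrics import CVConfig, build_model_suite, encode_da_targets, select_top_features
from .data_model import (
    ActivityTable,
    FeatureTable,
    assign_classes,
    load_activity_table,
    load_feature_table,
    uv_scale,
)
from .synthetic import SyntheticConfig, generate
from .validity import DEFAULT_THRESHOLDS, ValidityReport, gate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    feature_table: str | None = None
    feature_meta: str | None = None
    activity_table: str | None = None
    synthetic: SyntheticConfig | None = None
    cv: CVConfig = field(default_factory=CVConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    k_top: int = 25
    n_perm_validity: int = 20
    n_perm_importance: int = 100
    stat_vote_pct: float = 50.0
    stat_vote_strict: bool = True
    ml_vote_pct: float = 50.0
    ml_vote_strict: bool = False
    augment_to: int = 50
    mz_tol_mode: str = "exact3dp"
    ppm_tol: float = 10.0
    group_cut: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "cv" in raw and raw["cv"] is not None:
            raw["cv"] = CVConfig(**raw["cv"])
        return cls(**raw)


@dataclass
class ConsensusResult:
    stat_selected: set[str]
    ml_selected: set[str]
    final_features: list[str]
    final_compounds: list[tuple[float, list[str]]]

    @property
    def n_compounds(self) -> int:
        return len(self.final_compounds)


@dataclass
class PipelineResult:
    consensus: ConsensusResult
    validity_reports: list[ValidityReport]
    stat_vote: cns.VoteResult
    ml_vote: cns.VoteResult
    stat_lists: dict[str, list[str]]
    ml_lists: list[ml.ImportanceList]
    performance: pd.DataFrame
    feature_groups: list[set[str]]
    activity_correlation: pd.DataFrame
    manifest: dict


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("gate", "split", "split_boot", "importance", "augment")
    states = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s) % (2**31 - 1) for n, s in zip(names, states)}


def run_statistical_branch(
    table: FeatureTable,
    activity: ActivityTable,
    config: PipelineConfig,
    seed: int,
) -> tuple[list[ValidityReport], dict[str, list[str]], cns.VoteResult]:
    X = uv_scale(table)
    targets = {name: activity.target(name) for name in ("inv_agi", "ic50_agi", "inv_dpph", "ic50_dpph")}
    da = encode_da_targets(assign_classes(table))
    specs = build_model_suite()
    reports, models = gate(
        specs, X.values, targets, da, config.cv,
        seed=seed, n_perm=config.n_perm_validity, thresholds=config.thresholds,
    )
    spec_by_id = {s.model_id: s for s in specs}
    top_lists: dict[str, list[str]] = {}
    for rep in reports:
        if not rep.valid:
            continue
        spec = spec_by_id[rep.model_id]
        # orientation target: the model's first continuous target (inv_agi for
        # DA models that name one), falling back to inv_agi
        t_name = spec.y_spec[0] if spec.y_spec else "inv_agi"
        top_lists[rep.model_id] = select_top_features(
            models[rep.model_id], targets[t_name], X.var_ids, k=config.k_top
        )
    if top_lists:
        vote_res = cns.vote(list(top_lists.values()), config.stat_vote_pct, config.stat_vote_strict)
    else:
        vote_res = cns.VoteResult({}, 1, config.stat_vote_pct, config.stat_vote_strict)
        logger.warning("no valid projection model; statistical branch is empty")
    return reports, top_lists, vote_res


def run_ml_branch(
    table: FeatureTable,
    activity: ActivityTable,
    config: PipelineConfig,
    seeds: dict[str, int],
) -> tuple[pd.DataFrame, list[ml.ImportanceList], cns.VoteResult, pd.Series]:
    X = table.responses
    y = activity.inv_agi
    strata = table.ethanol_pct
    perf_plain = ml.compare_methods(
        X, y, ml.SplitConfig(seed=seeds["split"]), strata=strata, seed=seeds["split"]
    )
    perf_plain.insert(0, "bootstrap", False)
    perf_boot = ml.compare_methods(
        X, y, ml.SplitConfig(seed=seeds["split_boot"]), strata=strata,
        augment_to=config.augment_to, seed=seeds["split_boot"],
    )
    perf_boot.insert(0, "bootstrap", True)
    performance = pd.concat([perf_plain, perf_boot], ignore_index=True)

    corr_list, corr_full = ml.correlation_ranking(X, y, table.var_ids, k=config.k_top)
    rf_lists = ml.rf_importance_lists(
        X, y, table.var_ids, strata=strata,
        n_perm=config.n_perm_importance, k=config.k_top,
        augment_to=config.augment_to, seed=seeds["importance"],
    )
    screened = [ml.sign_screen(lst, corr_full) for lst in rf_lists + [corr_list]]
    vote_res = cns.vote([lst.var_ids for lst in screened], config.ml_vote_pct, config.ml_vote_strict)
    return performance, screened, vote_res, corr_full


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    t0 = time.time()
    if config.synthetic is not None:
        table, activity, _truth = generate(config.synthetic)
        source = {"synthetic": dataclasses.asdict(config.synthetic)}
    else:
        if config.feature_table is None or config.activity_table is None:
            raise ValueError("provide either a synthetic config or input CSV paths")
        table = load_feature_table(config.feature_table, config.feature_meta)
        activity = load_activity_table(config.activity_table)
        source = {
            "feature_table": _checksum(config.feature_table),
            "activity_table": _checksum(config.activity_table),
        }
    seeds = _stage_seeds(config.seed)

    logger.info("branch A: projection suite on %d x %d", table.n_samples, table.n_features)
    reports, stat_lists, stat_vote = run_statistical_branch(table, activity, config, seeds["gate"])
    logger.info("branch A done: %d/%d valid models (%.1f s)",
                sum(r.valid for r in reports), len(reports), time.time() - t0)

    performance, ml_lists, ml_vote, corr_full = run_ml_branch(table, activity, config, seeds)
    logger.info("branch B done (%.1f s)", time.time() - t0)

    final = cns.intersect(stat_vote.selected, ml_vote.selected)
    mz_map = dict(zip(table.var_ids, table.mz))
    compounds = cns.merge_by_mz(
        [(v, mz_map[v]) for v in final], config.mz_tol_mode, config.ppm_tol
    )
    result_sets = ConsensusResult(stat_vote.selected, ml_vote.selected, final, compounds)

    top_pos = corr_full.sort_values(ascending=False).head(config.k_top).index.tolist()
    idx = [table.var_ids.index(v) for v in top_pos]
    corr_mat = cns.correlation_matrix(table.responses[:, idx], top_pos)
    groups = cns.group_features(corr_mat, cut=config.group_cut)
    act_corr = cns.activity_cross_correlation(activity)

    manifest = {
        "config": _config_dict(config),
        "source": source,
        "stage_seeds": seeds,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "wall_time_s": round(time.time() - t0, 2),
        "n_samples": table.n_samples,
        "n_features": table.n_features,
    }
    result = PipelineResult(
        consensus=result_sets,
        validity_reports=reports,
        stat_vote=stat_vote,
        ml_vote=ml_vote,
        stat_lists=stat_lists,
        ml_lists=ml_lists,
        performance=performance,
        feature_groups=groups,
        activity_correlation=act_corr,
        manifest=manifest,
    )
    if out_dir is not None:
        write_reports(result, table, Path(out_dir))
    return result


def worked_example() -> ConsensusResult:
    """Intersect the bundled case-study branch lists and merge by m/z."""
    from . import datasets

    stat = datasets.load_stat_branch()
    mlb = datasets.load_ml_branch()
    final = cns.intersect(set(stat["var_id"]), set(mlb["var_id"]))
    mz_map = dict(zip(stat["var_id"], stat["mz"])) | dict(zip(mlb["var_id"], mlb["mz"]))
    compounds = cns.merge_by_mz([(v, float(mz_map[v])) for v in final])
    return ConsensusResult(
        stat_selected=set(stat["var_id"]),
        ml_selected=set(mlb["var_id"]),
        final_features=final,
        final_compounds=compounds,
    )


# -- reporting ----------------------------------------------------------------


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def write_reports(result: PipelineResult, table: FeatureTable, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "model_id": r.model_id, "r2y": r.r2y, "q2": r.q2, "diff": r.diff,
            "r2_intercept": r.r2_intercept, "q2_intercept": r.q2_intercept,
            "cvanova_p_max": max(r.cvanova_p) if r.cvanova_p else float("nan"),
            "n_components": r.n_components, "n_orth": r.n_orth, "valid": r.valid,
        }
        for r in result.validity_reports
    ]
    pd.DataFrame(rows).to_csv(out_dir / "validity.csv", index=False)
    result.stat_vote.to_frame().to_csv(out_dir / "stat_vote.csv", index=False)
    result.ml_vote.to_frame().to_csv(out_dir / "ml_vote.csv", index=False)
    result.performance.to_csv(out_dir / "ml_performance.csv", index=False)
    mz_map = dict(zip(table.var_ids, table.mz))
    pd.DataFrame(
        {
            "var_id": result.consensus.final_features,
            "mz": [mz_map[v] for v in result.consensus.final_features],
        }
    ).to_csv(out_dir / "final_features.csv", index=False)
    pd.DataFrame(
        [
            {"mz": mz, "members": ";".join(mem)}
            for mz, mem in result.consensus.final_compounds
        ]
    ).to_csv(out_dir / "final_compounds.csv", index=False)
    result.activity_correlation.to_csv(out_dir / "activity_correlation.csv")
    manifest = dict(result.manifest)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
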
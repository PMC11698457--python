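"""Synthetic LC-MS study generator with planted ground truth.

Emulates the design the pipeline was built for: 5 extraction-solvent classes
(0/25/50/75/100 % ethanol) x 6 replicates = 30 extract samples, 80 m/z
features, and two bioassay activities (AGI and DPPH) driven by a planted set
of features.  Peak responses follow a log-normal class-mean model:

    log R_ij = b_j + trend_j * e_i + lambda_block * f_{g(j),i} + eps_ij

where ``e_i`` is the ethanol fraction of sample i, ``f`` are per-sample
latent factors shared within a correlation block (inducing the blocky
correlation structure real metabolite families show), and ``eps`` is
replicate noise.  Planted *active* features trend up with ethanol, planted
*negative* features trend down, so the 100 %-ethanol class is the most
active by construction and the discriminant class split is learnable.

Activity is generated on the 1/IC50 scale (the scale the pipeline regresses
on) and then inverted; a positive affine placement keeps every IC50 > 0 and
the reciprocal roughly linear in the underlying activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ActivityTable, FeatureMeta, FeatureTable, SampleMeta

_ETHANOL_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)


def _default_active() -> list[int]:
    return list(range(40, 50))  # Var41..Var50


def _default_negative() -> list[int]:
    return [4, 7, 10]  # Var5, Var8, Var11


def _default_blocks() -> list[list[int]]:
    # two blocks inside the planted actives plus one mixed block anchored on
    # the last active, mirroring the three correlation groups the consensus
    # stage is expected to recover
    return [list(range(40, 46)), list(range(46, 49)), [49, 1, 2, 5, 6, 9]]


@dataclass
class SyntheticConfig:
    """Study-design parameters for one simulated dataset."""

    n_classes: int = 5
    replicates_per_class: int = 6
    n_features: int = 80
    active_features: list[int] = field(default_factory=_default_active)
    negative_features: list[int] = field(default_factory=_default_negative)
    correlation_blocks: list[list[int]] = field(default_factory=_default_blocks)
    rho_block: float = 0.9
    #: multiplier on the ethanol trend of planted features (log units over the
    #: full solvent gradient); the default places single-feature correlations
    #: with 1/IC50 AGI in the 0.5-0.85 band typical of the study design.
    effect_size: float = 3.0
    #: sd of the additive noise on the latent activity (signal sd is ~5-7).
    noise_sd: float = 5.0
    #: sd of the random ethanol trend of non-planted features (log units over
    #: the gradient).  Extraction yields of most metabolites vary with solvent
    #: polarity, which gives real feature tables a low effective rank; leaving
    #: this at 0 would make the 80 features nearly independent, something an
    #: extract-gradient study never shows.
    background_trend_sd: float = 0.35
    #: shared sample-level factors loading on every feature (matrix effects,
    #: day-to-day extraction state); together with the trends these dominate
    #: the small replicate noise, as they do in real peak tables.
    n_global_factors: int = 3
    global_loading_sd: float = 0.3
    #: replicate (technical) noise sd on the log scale, ~ LC-MS repeatability.
    replicate_noise_sd: float = 0.03
    #: sd of the within-block latent factor (log units).  None derives it
    #: from rho_block against the non-trend variance; a fixed value sets the
    #: balance between gradient-driven and family-driven variation directly.
    block_factor_sd: float | None = 0.5
    base_response_scale: float = 1e4
    active_weight: float = 1.0
    negative_weight: float = 1.0
    #: pair of active-list positions given an identical m/z (one compound
    #: detected as two features); None disables the duplication.
    duplicate_mz_pair: tuple[int, int] | None = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_class < 2:
            raise ValueError("replicates_per_class must be >= 2")
        planted = set(self.active_features) | set(self.negative_features)
        if set(self.active_features) & set(self.negative_features):
            raise ValueError("active and negative feature sets must be disjoint")
        if any(j < 0 or j >= self.n_features for j in planted):
            raise ValueError("planted feature index out of range")
        for block in self.correlation_blocks:
            if any(j < 0 or j >= self.n_features for j in block):
                raise ValueError("correlation-block index out of range")

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.replicates_per_class


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    active_set: list[str]
    negative_set: list[str]
    block_assignment: dict[str, int]
    true_activity: np.ndarray


def generate(config: SyntheticConfig) -> tuple[FeatureTable, ActivityTable, GroundTruth]:
    """Draw one dataset; bitwise deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features

    levels = _ETHANOL_LEVELS[: config.n_classes]
    if config.n_classes > len(_ETHANOL_LEVELS):
        levels = tuple(np.linspace(0.0, 100.0, config.n_classes))
    ethanol = np.repeat(levels, config.replicates_per_class)
    e = ethanol / 100.0

    trend = rng.normal(scale=config.background_trend_sd, size=p)
    trend[config.active_features] = config.effect_size
    trend[config.negative_features] = -config.effect_size

    block_of = np.full(p, -1)
    for g, block in enumerate(config.correlation_blocks):
        block_of[block] = g

    # block-factor loading chosen so that, net of the shared ethanol trend,
    # the within-block correlation is rho_block; the non-trend variance a
    # feature carries is global-factor plus replicate variance, so the factor
    # must dominate that total, not just the (small) replicate noise.  This
    # also gives activity a within-class component: compound families vary
    # between replicate extractions and the bioactivity follows the
    # compounds, which is what lets any method separate planted actives from
    # features that merely track the solvent gradient.
    resid_var = config.replicate_noise_sd**2
    if config.block_factor_sd is not None:
        lam = config.block_factor_sd
    else:
        nontrend_var = resid_var + config.n_global_factors * config.global_loading_sd**2
        lam = np.sqrt(config.rho_block / (1.0 - config.rho_block) * nontrend_var)

    base = rng.normal(np.log(config.base_response_scale), 0.5, size=p)
    factors = rng.normal(size=(n, len(config.correlation_blocks)))
    global_factors = rng.normal(size=(n, config.n_global_factors))
    global_load = rng.normal(scale=config.global_loading_sd, size=(config.n_global_factors, p))
    eps = rng.normal(scale=np.sqrt(resid_var), size=(n, p))
    log_r = base[None, :] + np.outer(e, trend) + global_factors @ global_load + eps
    for g in range(len(config.correlation_blocks)):
        log_r[:, block_of == g] += lam * factors[:, [g]]
    responses = np.exp(log_r)

    def zscore(m: np.ndarray) -> np.ndarray:
        return (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)

    z = zscore(responses)
    signal = config.active_weight * z[:, config.active_features].sum(axis=1)
    signal -= config.negative_weight * z[:, config.negative_features].sum(axis=1)
    true_activity = signal + rng.normal(scale=config.noise_sd, size=n)
    dpph_activity = signal + rng.normal(scale=config.noise_sd, size=n)

    def to_inv(act: np.ndarray) -> np.ndarray:
        s = act.std(ddof=1)
        scaled = (act - act.mean()) / s if s > 0 else act - act.mean()
        return 2.0 + 0.5 * scaled  # 1/IC50 kept well away from 0

    inv_agi = to_inv(true_activity)
    inv_dpph = to_inv(dpph_activity)

    mz = np.round(rng.uniform(150.0, 1000.0, size=p), 3)
    while len(np.unique(mz)) < p:  # distinct by construction, then duplicated on purpose
        mz = np.round(rng.uniform(150.0, 1000.0, size=p), 3)
    if config.duplicate_mz_pair is not None and len(config.active_features) >= 2:
        i, j = config.duplicate_mz_pair
        a = config.active_features
        mz[a[j % len(a)]] = mz[a[i % len(a)]]

    samples = [
        SampleMeta(f"S-{int(ethanol[i])}-{i % config.replicates_per_class + 1}", ethanol[i], i % config.replicates_per_class + 1)
        for i in range(n)
    ]
    features = [FeatureMeta(f"Var{j + 1}", float(mz[j])) for j in range(p)]
    table = FeatureTable(samples, features, responses)
    activity = ActivityTable(
        sample_id=table.sample_ids,
        ic50_agi=1.0 / inv_agi,
        ic50_dpph=1.0 / inv_dpph,
    )
    truth = GroundTruth(
        active_set=[f"Var{j + 1}" for j in config.active_features],
        negative_set=[f"Var{j + 1}" for j in config.negative_features],
        block_assignment={f"Var{j + 1}": int(block_of[j]) for j in range(p) if block_of[j] >= 0},
        true_activity=true_activity,
    )
    return table, activity, truth
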
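"""Synthetic cell-line and xenograft cohorts with planted ground truth.

The generator emulates the statistical structure the biomarker analysis
assumes: block-correlated log-scale expression for coding and lincRNA
features (shared latent factor per block), a sparse linear signature driving
log10 rIC50 with additive Gaussian noise calibrated to a target R^2, an
optional bimodal "transporter" resistance feature whose effect on
sensitivity is non-linear (expressed only in the high-state subpopulation --
the documented blind spot of a linear screen), copy number coupled to
expression for a chosen subset of genes, and xenograft tumor-volume
trajectories whose per-animal kill rate is a monotone (logistic) function of
the same signature score. Every output is bit-reproducible from the seed.

Growth model: tumors grow exponentially at a per-animal rate g_i (lognormal
jitter around ln2/doubling_days); treatment applies an additional kill rate
d_i during a treatment window, after which regrowth resumes:

    V(t) = V0_i * exp(g_i * t - d_i * min(t, treatment_days))

with multiplicative lognormal measurement noise at each observation day,
baseline included. d_i = d_max * logistic(-kappa * z_i) where z_i is the
cohort-standardized resistance score, so predicted-sensitive tumors are
killed fastest. Control animals share the growth model with d = 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import (
    CopyNumberMatrix,
    ExpressionMatrix,
    FeatureAnnotation,
    SensitivityProfile,
)
from .response import ResponseClass, VolumeSeries, classify_individual, event_free_survival

__all__ = [
    "TransporterConfig",
    "GrowthConfig",
    "CnvConfig",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedCohort",
    "CnvResult",
    "simulate_cohort",
    "generate_cnv",
    "classify_cohort",
    "class_census",
]


@dataclass
class TransporterConfig:
    """Bimodal non-linear resistance feature (efflux-transporter analogue).

    ``prevalence`` is the fraction of samples in the high-expression state;
    ``shift`` the log10 rIC50 increase those samples incur; ``separation``
    the distance between the two expression modes in within-mode sd units.
    """

    prevalence: float = 0.3
    shift: float = 2.0
    separation: float = 2.0
    feature_id: str = "XPORT1"


@dataclass
class GrowthConfig:
    """Tumor growth, treatment, and measurement parameters."""

    v0_mm3: float = 300.0          # median enrollment volume
    baseline_sigma: float = 0.3    # lognormal sd of per-animal baseline
    doubling_days: float = 7.0
    treatment_days: float = 36.0   # median duration of drug effect
    treatment_sigma: float = 0.2   # lognormal jitter on that duration
    study_days: float = 42.0
    obs_days: tuple = (0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42)
    noise_sd: float = 0.12         # lognormal measurement noise
    growth_sigma: float = 0.3      # per-animal lognormal jitter on g
    kill_steepness: float = 1.0    # logistic steepness kappa
    d_max_factor: float = 2.0      # d_max = factor * g
    n_treated: int = 4             # animals per treated group
    n_control: int = 4             # animals per control group

    @property
    def growth_rate(self) -> float:
        return np.log(2.0) / self.doubling_days

    @property
    def d_max(self) -> float:
        return self.d_max_factor * self.growth_rate


@dataclass
class CnvConfig:
    n_coupled: int = 10
    coupling_rho: float = 0.9
    scale_log2: float = 0.5  # sd of log2 copy-number ratios


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort."""

    seed: int = 0
    n_cell_lines: int = 22
    n_xenografts: int = 40
    p_coding: int = 3000
    p_linc: int = 500
    block_size: int = 10
    block_rho: float = 0.5
    k_signal: int = 10
    effect_low: float = 0.3
    effect_high: float = 1.0
    target_r2: float = 0.7
    y_center: float = -7.5  # log10 molar, ~32 nM
    agent: str = "agentX"
    transporter: Optional[TransporterConfig] = None
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)

    def __post_init__(self) -> None:
        if self.k_signal > self.p_coding + self.p_linc:
            raise ValueError("k_signal exceeds the number of features")
        if not (0 < self.target_r2 < 1):
            raise ValueError("target_r2 must lie in (0, 1)")
        for name in ("n_cell_lines", "n_xenografts", "p_coding",
                     "block_size", "k_signal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_linc < 0:
            raise ValueError("p_linc must be >= 0")

    @property
    def p_total(self) -> int:
        return self.p_coding + self.p_linc


@dataclass
class TruthRecord:
    """Ground truth for recovery testing."""

    planted_features: list[str]
    betas: np.ndarray
    score_cells: np.ndarray
    score_xeno: np.ndarray
    kill_rates: np.ndarray
    noise_sd: float
    transporter_cells: Optional[np.ndarray]  # boolean high-state, or None
    transporter_xeno: Optional[np.ndarray]
    seed: int


@dataclass
class SimulatedCohort:
    cells: ExpressionMatrix
    sensitivities: list[SensitivityProfile]
    xeno: ExpressionMatrix
    volumes: list[VolumeSeries]
    truth: TruthRecord
    config: SimulationConfig


@dataclass
class CnvResult:
    matrix: CopyNumberMatrix
    coupled_ids: list[str]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _make_features(config: SimulationConfig) -> list[FeatureAnnotation]:
    """Feature annotations laid out block-contiguously along chromosomes."""
    feats = []
    chrom_count = 22
    spacing = 50_000
    length = 2_000
    for j in range(config.p_total):
        block = j // config.block_size
        chrom = f"chr{(block % chrom_count) + 1}"
        start = 1 + (j // chrom_count // config.block_size * config.block_size
                     + j % config.block_size) * spacing
        biotype = "coding" if j < config.p_coding else "lincRNA"
        feats.append(
            FeatureAnnotation(
                feature_id=(f"G{j + 1:05d}" if biotype == "coding"
                            else f"LINC{j - config.p_coding + 1:04d}"),
                biotype=biotype,
                chrom=chrom,
                start=start,
                end=start + length - 1,
                strand="+" if j % 2 == 0 else "-",
            )
        )
    return feats


def _latent_block_matrix(
    rng: np.random.Generator, p: int, n: int, block_size: int, rho: float
) -> np.ndarray:
    """Standardized latent values with within-block correlation rho via a
    shared factor per block."""
    n_blocks = -(-p // block_size)
    factors = rng.standard_normal((n_blocks, n))
    noise = rng.standard_normal((p, n))
    block_of = np.arange(p) // block_size
    return np.sqrt(rho) * factors[block_of] + np.sqrt(1.0 - rho) * noise


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate aligned cell-line and xenograft cohorts with ground truth."""
    (rng_feat, rng_cells, rng_xeno, rng_effects, rng_noise,
     rng_trans, rng_growth) = _substreams(config.seed, 7)

    features = _make_features(config)
    p = config.p_total

    # feature-level location/scale, shared across cohorts (same platform)
    mu = rng_feat.normal(8.0, 1.5, size=p)
    sigma = rng_feat.uniform(0.5, 1.5, size=p)

    z_cells = _latent_block_matrix(
        rng_cells, p, config.n_cell_lines, config.block_size, config.block_rho
    )
    z_xeno = _latent_block_matrix(
        rng_xeno, p, config.n_xenografts, config.block_size, config.block_rho
    )

    # planted sparse signature: one feature in each of k distinct blocks
    n_blocks = -(-p // config.block_size)
    if config.k_signal > n_blocks:
        raise ValueError(
            f"k_signal={config.k_signal} exceeds the {n_blocks} correlation "
            "blocks (one planted feature per block)"
        )
    blocks = rng_effects.choice(n_blocks, size=config.k_signal, replace=False)
    planted_idx = np.array(
        [b * config.block_size
         + rng_effects.integers(min(config.block_size, p - b * config.block_size))
         for b in blocks]
    )
    betas = rng_effects.uniform(config.effect_low, config.effect_high,
                                size=config.k_signal)
    betas *= rng_effects.choice([-1.0, 1.0], size=config.k_signal)

    s_cells = betas @ z_cells[planted_idx]
    s_xeno = betas @ z_xeno[planted_idx]

    # noise calibrated so that var(signal)/var(y) ~= target_r2
    sd_signal = float(np.std(s_cells, ddof=1))
    noise_sd = sd_signal * np.sqrt((1.0 - config.target_r2) / config.target_r2)
    y_cells = config.y_center + s_cells + rng_noise.normal(0.0, noise_sd,
                                                           config.n_cell_lines)

    cell_ids = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    xeno_ids = [f"X{i + 1:03d}" for i in range(config.n_xenografts)]

    cells_vals = mu[:, None] + sigma[:, None] * z_cells
    xeno_vals = mu[:, None] + sigma[:, None] * z_xeno

    trans_cells = trans_xeno = None
    resistance_xeno = s_xeno.copy()
    if config.transporter is not None:
        tc = config.transporter
        trans_cells = rng_trans.random(config.n_cell_lines) < tc.prevalence
        trans_xeno = rng_trans.random(config.n_xenografts) < tc.prevalence
        expr_c = 7.0 + tc.separation * trans_cells + rng_trans.standard_normal(
            config.n_cell_lines)
        expr_x = 7.0 + tc.separation * trans_xeno + rng_trans.standard_normal(
            config.n_xenografts)
        features = features + [
            FeatureAnnotation(feature_id=tc.feature_id, biotype="coding",
                              chrom="chr7", start=1, end=2000, strand="+")
        ]
        cells_vals = np.vstack([cells_vals, expr_c])
        xeno_vals = np.vstack([xeno_vals, expr_x])
        y_cells = y_cells + tc.shift * trans_cells
        resistance_xeno = resistance_xeno + tc.shift * trans_xeno

    cells = ExpressionMatrix(features, cell_ids, cells_vals)
    xeno = ExpressionMatrix(features, xeno_ids, xeno_vals)

    sensitivities = [
        SensitivityProfile(agent=config.agent, sample_id=sid,
                           ric50=float(10.0**y), censored=False)
        for sid, y in zip(cell_ids, y_cells)
    ]

    # kill rates: monotone decreasing in the resistance score
    g = config.growth
    z_r = (resistance_xeno - resistance_xeno.mean())
    sd_r = resistance_xeno.std()
    if sd_r > 0:
        z_r = z_r / sd_r
    kill = g.d_max / (1.0 + np.exp(g.kill_steepness * z_r))

    volumes = _simulate_volumes(rng_growth, xeno_ids, kill, g)

    truth = TruthRecord(
        planted_features=[features[j].feature_id for j in planted_idx],
        betas=betas,
        score_cells=s_cells,
        score_xeno=s_xeno,
        kill_rates=kill,
        noise_sd=float(noise_sd),
        transporter_cells=trans_cells,
        transporter_xeno=trans_xeno,
        seed=config.seed,
    )
    return SimulatedCohort(
        cells=cells, sensitivities=sensitivities, xeno=xeno,
        volumes=volumes, truth=truth, config=config,
    )


def _simulate_volumes(
    rng: np.random.Generator,
    xeno_ids: Sequence[str],
    kill: np.ndarray,
    g: GrowthConfig,
) -> list[VolumeSeries]:
    days = np.asarray(g.obs_days, dtype=float)
    rate = g.growth_rate
    out = []
    for model_id, d in zip(xeno_ids, kill):
        animals = [("treated", f"T{i + 1}", d) for i in range(g.n_treated)] + [
            ("control", f"C{i + 1}", 0.0) for i in range(g.n_control)
        ]
        for arm, suffix, kill_rate in animals:
            v0 = g.v0_mm3 * rng.lognormal(0.0, g.baseline_sigma)
            gi = rate * rng.lognormal(0.0, g.growth_sigma)
            t_eff = min(
                g.treatment_days * rng.lognormal(0.0, g.treatment_sigma),
                g.study_days,
            )
            true_v = v0 * np.exp(
                gi * days - kill_rate * np.minimum(days, t_eff)
            )
            measured = true_v * rng.lognormal(0.0, g.noise_sd, size=len(days))
            out.append(
                VolumeSeries(
                    model_id=model_id, arm=arm,
                    animal_id=f"{model_id}-{suffix}",
                    days=days, volumes=measured,
                )
            )
    return out


def generate_cnv(config: SimulationConfig, expr: ExpressionMatrix) -> CnvResult:
    """Log2 copy-number ratios, coupled to expression for a chosen subset.

    Coupled genes follow cnv = rho * z_expr + sqrt(1 - rho^2) * noise on the
    standardized scale; all others are independent noise. Only coding
    features participate.
    """
    c = config.cnv
    if not (0 <= c.coupling_rho <= 1):
        raise ValueError("coupling_rho must lie in [0, 1]")
    rng = _substreams(config.seed, 8)[7]
    coding = [f for f in expr.features if f.biotype == "coding"]
    n_coupled = min(c.n_coupled, len(coding))
    coupled_ids = sorted(
        rng.choice([f.feature_id for f in coding], size=n_coupled, replace=False)
    )
    coupled = set(coupled_ids)
    vals = np.empty((len(coding), expr.shape[1]))
    pos = {f: i for i, f in enumerate(expr.feature_ids)}
    for i, f in enumerate(coding):
        row = expr.values[pos[f.feature_id]]
        sd = row.std(ddof=1)
        z = (row - row.mean()) / sd if sd > 0 else np.zeros_like(row)
        eta = rng.standard_normal(expr.shape[1])
        if f.feature_id in coupled:
            vals[i] = c.scale_log2 * (
                c.coupling_rho * z + np.sqrt(1 - c.coupling_rho**2) * eta
            )
        else:
            vals[i] = c.scale_log2 * eta
    matrix = CopyNumberMatrix(coding, expr.sample_ids, vals)
    return CnvResult(matrix=matrix, coupled_ids=list(coupled_ids))


def classify_cohort(
    volumes: Sequence[VolumeSeries],
    study_end: float = 42.0,
    measurable_mm3: float = 100.0,
    event_rtv: float = 4.0,
) -> dict[str, ResponseClass]:
    """Classify each model's treated animals against its control arm.

    The control arm provides the median event-free survival used for the
    PD1/PD2 growth-delay split; models without controls are classified
    without it (PD2 never assigned).
    """
    by_model: dict[str, dict[str, list[VolumeSeries]]] = {}
    for s in volumes:
        by_model.setdefault(s.model_id, {"control": [], "treated": []})[s.arm].append(s)
    out: dict[str, ResponseClass] = {}
    for model_id, arms in by_model.items():
        if not arms["treated"]:
            continue
        control_median = None
        if arms["control"]:
            efs = [event_free_survival(c, event_rtv).time for c in arms["control"]]
            control_median = float(np.median(efs))
        classes = [
            classify_individual(
                t, study_end=study_end, measurable_mm3=measurable_mm3,
                control_median_efs=control_median, event_rtv=event_rtv,
            )
            for t in arms["treated"]
        ]
        # single-animal groups are their own median; larger groups aggregate
        scores = sorted(c.score for c in classes)
        n = len(scores)
        med = (scores[n // 2] if n % 2 else (scores[n // 2 - 1] + scores[n // 2]) / 2)
        out[model_id] = {c.value: c for c in ResponseClass}[int(med // 2) * 2]
    return out


def class_census(
    volumes: Sequence[VolumeSeries],
    study_end: float = 42.0,
    measurable_mm3: float = 100.0,
    event_rtv: float = 4.0,
) -> dict[ResponseClass, int]:
    """Counts per response class over the cohort; counts sum to the number
    of classified models."""
    classes = classify_cohort(volumes, study_end, measurable_mm3, event_rtv)
    census = Counter(classes.values())
    return {c: census.get(c, 0) for c in ResponseClass}
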
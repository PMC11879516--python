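"""Synthetic study generator.

Produces the three inputs of the analysis pipeline without any external
data: (1) a subjects × SNPs dosage matrix with block-structured LD, (2)
GWAS-like summary statistics over the same SNP map, and (3) a week of
hierarchical experience-sampling data whose next-beep outcomes follow a
configurable crossover-form G×E regime

    y_{i,t+1} = b0 + u_i + (s0 + s1·G_i)·(E_{i,t} − c) + e_{i,t+1}

with subject random intercepts u_i and the environment E taken from the
momentary context item of the *current* beep.  Lagged structure is generated
only between consecutive beeps of the same day; the first beep of a day
carries no dependence on the previous evening.

The generator mirrors the design of a one-week ESM protocol: eight random
signals per day between 10 a.m. and 10 p.m., consecutive signals 10–170
minutes apart, items on 1–7 scales with strong floor effects on symptom
outcomes, and Bernoulli compliance calibrated so the expected number of
completed questionnaires per subject is ~40.7 of the 56 issued.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .esm import DEFAULT_INDICES, IndexDefinition
from .gxe import GxeModelSpec
from .prs import GenotypeDosageMatrix, GwasSummaryStats, PrsProfile

__all__ = [
    "CrossoverParams",
    "SynthConfig",
    "TrueParamRecord",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_esm",
]

# Beta shapes for the two context-appraisal presets, calibrated so that the
# discretized 1–7 draws have means near 2.15 (stressful; >50% floor) and
# 5.35 (positive)
CONTEXT_PRESETS: dict[str, tuple[float, float]] = {
    "stressful": (0.25, 1.0),
    "positive": (3.4, 1.3),
}

# baseline latent levels for outcome indices not driven by the G×E regime,
# chosen near observed person-mean levels of a non-clinical young-adult
# sample (symptom indices hug the scale floor; positive affect sits high)
DEFAULT_BASELINES: dict[str, float] = {
    "paranoia": 1.2,
    "ple": 1.1,
    "negative_like": 1.35,
    "na": 1.5,
    "pa": 4.7,
}

OUTCOME_INDICES: tuple[IndexDefinition, ...] = tuple(
    d for d in DEFAULT_INDICES if d.name in DEFAULT_BASELINES
)


@dataclass(frozen=True)
class CrossoverParams:
    """True parameters of the generative crossover regime."""

    b0: float = 1.2
    s0: float = -0.03
    s1: float = -0.02
    c: float = 5.0
    sigma_u: float = 0.25
    sigma_e: float = 0.35

    def __post_init__(self):
        if self.sigma_u < 0 or self.sigma_e <= 0:
            raise ValueError("sigma_u must be >= 0 and sigma_e > 0")


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_subjects: int = 217
    n_blocks: int = 20
    snps_per_block: int = 10
    block_corr: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    prop_causal: float = 0.3
    beta_sd: float = 0.05
    n_gwas: int = 20_000
    n_days: int = 7
    signals_per_day: int = 8
    window_minutes: tuple[int, int] = (600, 1320)
    min_gap_minutes: float = 10.0
    max_gap_minutes: float = 170.0
    compliance: float = 40.7 / 56.0
    compliance_sd: float = 0.15  # between-subject SD of the completion rate
    true_model: GxeModelSpec = field(
        default_factory=lambda: GxeModelSpec.make("differential_susceptibility", "weak")
    )
    true_params: CrossoverParams = field(default_factory=CrossoverParams)
    item_noise_sd: float = 0.25
    context: str = "positive"
    target_outcome: str = "paranoia"
    round_items: bool = True  # False = continuous test mode (no rounding/clipping)

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"invalid maf range {self.maf_range}: need 0 < low <= high <= 0.5")
        if not (0 <= self.block_corr < 1):
            raise ValueError("block_corr must lie in [0, 1)")
        if not (0 <= self.prop_causal <= 1):
            raise ValueError("prop_causal must lie in [0, 1]")
        if self.beta_sd < 0:
            raise ValueError("beta_sd must be >= 0")
        w0, w1 = self.window_minutes
        if not w0 < w1:
            raise ValueError("window start must precede end")
        if not 0 < self.min_gap_minutes < self.max_gap_minutes:
            raise ValueError("need 0 < min_gap < max_gap")
        if not (0 < self.compliance <= 1):
            raise ValueError("compliance must lie in (0, 1]")
        if self.compliance_sd < 0:
            raise ValueError("compliance_sd must be >= 0")
        if (
            self.compliance_sd > 0
            and self.compliance < 1
            and self.compliance_sd**2 >= self.compliance * (1 - self.compliance)
        ):
            raise ValueError("compliance_sd too large for a Beta completion rate")
        if self.compliance * self.n_days * self.signals_per_day < 2:
            raise ValueError("expected completed beeps must be >= 2")
        if self.context not in CONTEXT_PRESETS:
            raise ValueError(f"context must be one of {sorted(CONTEXT_PRESETS)}")
        if self.target_outcome not in DEFAULT_BASELINES:
            raise ValueError(f"unknown target outcome {self.target_outcome!r}")
        if self.item_noise_sd < 0:
            raise ValueError("item_noise_sd must be >= 0")
        if self.true_model.strength == "strong" and self.true_params.s0 != 0.0:
            raise ValueError("a strong true model requires s0 = 0")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class TrueParamRecord:
    """Ground truth stored alongside the generated data for recovery tests."""

    g: pd.Series  # per-subject sensitivity score used in generation
    u: pd.Series  # per-subject random intercept of the target outcome
    context_value: np.ndarray  # true E per issued beep (row-aligned)
    latent_outcome: np.ndarray  # latent target-outcome value per issued beep
    params: CrossoverParams
    model: GxeModelSpec
    target_outcome: str
    context: str


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def simulate_genotypes(cfg: SynthConfig) -> GenotypeDosageMatrix:
    """Dosage matrix with equicorrelated latent-Gaussian LD blocks.

    Each haplotype's allele indicators within a block come from thresholding
    an equicorrelated Gaussian vector (correlation ``block_corr``) at the
    SNP's allele-frequency quantile; dosage is the sum of two independent
    haplotypes.  Blocks are placed ≥ 2000 kb apart so a 1000 kb clumping
    window never spans two blocks.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n, m_blk = cfg.n_subjects, cfg.snps_per_block
    rho = cfg.block_corr
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_blocks * m_blk)
    thresholds = sps.norm.ppf(mafs).reshape(cfg.n_blocks, m_blk)

    blocks = []
    for b in range(cfg.n_blocks):
        dose = np.zeros((n, m_blk))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            indep = rng.standard_normal((n, m_blk))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
            dose += (z < thresholds[b]).astype(float)
        blocks.append(dose)
    dosages = np.concatenate(blocks, axis=1)

    snp_ids, chrom, bp = [], [], []
    for b in range(cfg.n_blocks):
        for j in range(m_blk):
            snp_ids.append(f"snp_b{b:03d}_{j:03d}")
            chrom.append("1")
            bp.append(1_000_000 + b * 3_000_000 + j * 200)
    snp_map = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": bp,
            "a1": "A",
            "a2": "G",
            "maf": mafs,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeDosageMatrix(
        subject_ids=_subject_ids(n),
        snp_ids=snp_ids,
        dosages=dosages,
        snp_map=snp_map,
    )


def simulate_summary_stats(snp_map: pd.DataFrame, cfg: SynthConfig) -> GwasSummaryStats:
    """GWAS-like effect sizes and p-values over a SNP map.

    A SNP is causal with probability ``prop_causal`` and then reports
    beta ~ N(0, beta_sd²); a null SNP reports pure sampling noise at its
    per-SNP standard error 1/√(n_gwas·2·maf·(1−maf)).  P-values are
    two-sided normal tail areas of beta/SE, hence exactly uniform for null
    SNPs and strictly decreasing in |beta|·√(2·maf·(1−maf)).
    """
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    if "maf" not in snp_map.columns:
        raise ValueError("snp_map must carry a 'maf' column")
    rng = np.random.default_rng([cfg.seed, 1])
    m = len(snp_map)
    maf = snp_map["maf"].to_numpy(dtype=float)
    se = 1.0 / np.sqrt(cfg.n_gwas * 2.0 * maf * (1.0 - maf))
    causal = rng.random(m) < cfg.prop_causal
    beta_causal = rng.normal(0.0, cfg.beta_sd, size=m) if cfg.beta_sd > 0 else np.zeros(m)
    beta_null = rng.standard_normal(m) * se
    beta = np.where(causal, beta_causal, beta_null)
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    p = np.clip(p, 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "snp_id": snp_map.index,
            "chrom": snp_map["chrom"].to_numpy(),
            "bp": snp_map["bp"].to_numpy(),
            "a1": snp_map["a1"].to_numpy(),
            "a2": snp_map["a2"].to_numpy(),
            "beta": beta,
            "p": p,
        }
    ).reset_index(drop=True)
    return GwasSummaryStats(table)


def _draw_schedules(rng: np.random.Generator, n_schedules: int, cfg: SynthConfig) -> np.ndarray:
    """Signal times (minutes since midnight) for ``n_schedules`` subject-days.

    Rejection sampling of sorted uniforms on the signalling window until all
    consecutive gaps lie in [min_gap, max_gap]; times are integer minutes.
    """
    k = cfg.signals_per_day
    lo, hi = cfg.window_minutes
    if (k - 1) * cfg.min_gap_minutes > (hi - lo):
        raise ValueError(
            "impossible schedule: minimum gaps exceed the signalling window"
        )
    out = np.empty((n_schedules, k), dtype=int)
    filled = 0
    attempts = 0
    while filled < n_schedules:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("impossible schedule: gap constraints unsatisfiable")
        batch = max(n_schedules - filled, 64)
        t = np.sort(rng.uniform(lo, hi, size=(batch, k)), axis=1)
        t = np.rint(t).astype(int)
        gaps = np.diff(t, axis=1)
        ok = (
            (gaps >= cfg.min_gap_minutes).all(axis=1)
            & (gaps <= cfg.max_gap_minutes).all(axis=1)
        )
        good = t[ok]
        take = min(len(good), n_schedules - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _as_g_series(prs, cfg: SynthConfig) -> pd.Series:
    if isinstance(prs, PrsProfile):
        if len(prs.scores) != cfg.n_subjects:
            raise ValueError("PRS profile does not cover all subjects")
        g = prs.zscores(max(prs.thresholds))
        g.index.name = "subject_id"
        return g
    g = np.asarray(prs, dtype=float)
    if g.shape != (cfg.n_subjects,):
        raise ValueError("sensitivity score must have one value per subject")
    return pd.Series(g, index=pd.Index(_subject_ids(cfg.n_subjects), name="subject_id"))


def _discretize(x: np.ndarray, round_items: bool) -> np.ndarray:
    return np.clip(np.rint(x), 1, 7) if round_items else x


def simulate_esm(prs, cfg: SynthConfig) -> tuple[pd.DataFrame, TrueParamRecord]:
    """One week of beep-level ESM data under the configured G×E regime.

    ``prs`` is either a :class:`PrsProfile` (its most inclusive threshold is
    z-scored and used as the sensitivity score G) or an array of per-subject
    G values.  Returns the long table (one row per issued signal; items NaN
    when the beep was not completed) plus the ground-truth record.
    """
    g = _as_g_series(prs, cfg)
    subjects = list(g.index)
    rng = np.random.default_rng([cfg.seed, 2])
    n, d, k = cfg.n_subjects, cfg.n_days, cfg.signals_per_day
    pr = cfg.true_params

    times = _draw_schedules(rng, n * d, cfg).reshape(n, d, k)

    # momentary context appraisals, drawn per issued beep
    context_latent = {}
    for name, (a, b) in CONTEXT_PRESETS.items():
        context_latent[name] = _discretize(
            1.0 + 6.0 * rng.beta(a, b, size=(n, d, k)), cfg.round_items
        )
    e_ctx = context_latent[cfg.context]

    # latent outcomes: the target follows the crossover regime on the lag,
    # every other index is baseline + random intercept + noise
    u_target = rng.normal(0.0, pr.sigma_u, size=n)
    latent = {}
    for idx in OUTCOME_INDICES:
        if idx.name == cfg.target_outcome:
            eps = rng.normal(0.0, pr.sigma_e, size=(n, d, k))
            y = np.empty((n, d, k))
            y[:, :, 0] = pr.b0 + u_target[:, None] + eps[:, :, 0]
            slope = (pr.s0 + pr.s1 * g.to_numpy())[:, None, None]
            y[:, :, 1:] = (
                pr.b0
                + u_target[:, None, None]
                + slope * (e_ctx[:, :, :-1] - pr.c)
                + eps[:, :, 1:]
            )
        else:
            u = rng.normal(0.0, pr.sigma_u, size=n)
            eps = rng.normal(0.0, pr.sigma_e, size=(n, d, k))
            y = DEFAULT_BASELINES[idx.name] + u[:, None, None] + eps
        latent[idx.name] = y

    # item responses: latent index + item noise, discretized to the 1-7 grid
    items: dict[str, np.ndarray] = {}
    for idx in OUTCOME_INDICES:
        for col in idx.columns():
            noise = (
                rng.normal(0.0, cfg.item_noise_sd, size=(n, d, k))
                if cfg.item_noise_sd > 0
                else 0.0
            )
            items[col] = _discretize(latent[idx.name] + noise, cfg.round_items)
    items["item_situation_stressful"] = context_latent["stressful"]
    items["item_situation_positive"] = context_latent["positive"]

    # completion: Bernoulli per beep with a per-subject rate; heterogeneity
    # in the rate reproduces the large between-person spread of completed
    # questionnaires seen in real protocols
    if cfg.compliance_sd > 0 and cfg.compliance < 1:
        m, v = cfg.compliance, cfg.compliance_sd**2
        shape = m * (1 - m) / v - 1
        p_subject = rng.beta(m * shape, (1 - m) * shape, size=n)
    else:
        p_subject = np.full(n, cfg.compliance)
    observed = rng.random(size=(n, d, k)) < p_subject[:, None, None]

    rows = n * d * k
    subj_col = np.repeat(subjects, d * k)
    day_col = np.tile(np.repeat(np.arange(1, d + 1), k), n)
    beep_col = np.tile(np.arange(1, k + 1), n * d)
    obs_flat = observed.reshape(rows)
    data = {
        "subject_id": subj_col,
        "day": day_col,
        "beep": beep_col,
        "time_min": times.reshape(rows),
        "observed": obs_flat,
    }
    for col, arr in items.items():
        v = arr.reshape(rows).astype(float).copy()
        v[~obs_flat] = np.nan
        data[col] = v
    df = pd.DataFrame(data)

    record = TrueParamRecord(
        g=g,
        u=pd.Series(u_target, index=g.index),
        context_value=e_ctx.reshape(rows).astype(float),
        latent_outcome=latent[cfg.target_outcome].reshape(rows),
        params=pr,
        model=cfg.true_model,
        target_outcome=cfg.target_outcome,
        context=cfg.context,
    )
    return df, record
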
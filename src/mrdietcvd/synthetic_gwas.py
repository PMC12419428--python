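"""Synthetic GWAS summary statistics, LD regions, and expression matrices.

Every downstream stage of the pipeline is exercised on data from this module,
which emulates the statistical structure of the real sources (binary dietary
exposures with small per-variant effects, binary disease outcomes, an
LD-coherent region of about a megabase with a shared or distinct causal
variant, and a 111-case / 46-control two-group expression matrix) without any
external downloads.

Summary statistics are generated directly, not via individual-level
genotypes: per SNP the exposure effect is fixed at the size implied by its
per-instrument variance explained, the outcome effect is the causal effect
times the exposure effect plus a direct (pleiotropic) effect plus sampling
noise at the outcome standard error.  Standard errors follow the standard
1/sqrt(2·maf·(1−maf)·n) approximation for a standardized trait, reused on the
log-odds scale for binary traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import SnpAssociation, SumStatsTable, ValidationError

__all__ = [
    "MrSimConfig", "ColocSimConfig", "ExpressionSimConfig",
    "simulate_mr_pair", "simulate_coloc_region", "simulate_expression",
    "DEFAULT_EXPRESSION_EFFECTS",
]

#: Standardized case/control mean shifts for the six candidate genes at the
#: 1p13.3 locus, sized so the binormal AUC Phi(d/sqrt(2)) lands in the 0.65-0.72
#: band typical of single-gene blood-expression markers.
DEFAULT_EXPRESSION_EFFECTS: dict[str, float] = {
    "KIAA1324": 0.0,
    "SARS": 0.0,
    "CELSR2": 0.571,
    "PSRC1": 0.833,
    "MYBPHL": 0.649,
    "SORT1": 0.0,
}


@dataclass
class MrSimConfig:
    """Configuration for a simulated exposure/outcome GWAS pair.

    ``theta`` is the true causal effect of the exposure on the outcome (the
    quantity IVW estimates).  ``pleiotropy_mean``/``pleiotropy_sd`` control
    direct SNP-to-outcome effects: a nonzero mean is directional pleiotropy
    (biases IVW, recovered by the MR-Egger intercept); zero both ways gives
    valid instruments.  Defaults use biobank-scale sample sizes and a
    per-instrument variance explained giving instrument z-scores around 10,
    comfortably past the p < 5e-6 selection threshold.
    """

    n_snps: int = 30
    theta: float = 0.0
    n_exp: int = 200_000
    n_out: int = 200_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_per_snp: float = 5e-4
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if min(self.n_exp, self.n_out) < 100:
            raise ValidationError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if self.h2_per_snp < 0:
            raise ValidationError("h2_per_snp must be >= 0")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be >= 0")


@dataclass
class ColocSimConfig:
    """Configuration for a two-trait LD-coherent regional simulation.

    ``scenario`` picks the causal configuration: H0 no association, H1/H2 one
    trait only, H3 distinct causal variants, H4 a shared causal variant.
    ``effect_size_*`` are the non-centrality (expected z-score) of the causal
    variant; the default of 10 matches the magnitude seen at strong lipid loci.
    LD decays exponentially with index distance on a uniform position grid
    spanning a +/-500 kb window.
    """

    n_snps: int = 100
    ld_decay: float = 0.2
    scenario: str = "H4"
    effect_size_1: float = 10.0
    effect_size_2: float = 10.0
    n_1: int = 100_000
    n_2: int = 100_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    chrom: str = "1"
    center_pos: int = 1_000_000
    half_width_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValidationError(f"scenario {self.scenario!r} not in H0..H4")
        min_q = 2 if self.scenario == "H3" else 1
        if self.n_snps < min_q:
            raise ValidationError(f"n_snps must be >= {min_q} for {self.scenario}")
        if self.ld_decay < 0:
            raise ValidationError("ld_decay must be >= 0")


@dataclass
class ExpressionSimConfig:
    """Two-group expression matrix emulating a case/control blood microarray."""

    n_cases: int = 111
    n_controls: int = 46
    n_genes: int = 6
    effect_genes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_EFFECTS)
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls) < 2:
            raise ValidationError("group sizes must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, 1e-300)


def _make_table(
    trait_id: str, rsid, chrom, pos, beta, se, pval, eaf, n, n_case
) -> SumStatsTable:
    records = [
        SnpAssociation(
            rsid=rsid[j], chrom=str(chrom[j]), pos=int(pos[j]),
            effect_allele="A", other_allele="G",
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pval=float(pval[j]), n=float(n), n_case=float(n_case),
            trait_id=trait_id, trait_type="case_control",
        )
        for j in range(len(rsid))
    ]
    return SumStatsTable(trait_id=trait_id, records=records, provenance="simulated")


def simulate_mr_pair(
    cfg: MrSimConfig,
) -> tuple[SumStatsTable, SumStatsTable, dict]:
    """Simulate an exposure GWAS, an outcome GWAS, and the generating truth.

    Per SNP j: draw maf_j; fix the exposure effect at
    sqrt(h2_per_snp / (2·maf_j·(1−maf_j))) on the exposure-increasing allele
    with se 1/sqrt(2·maf_j·(1−maf_j)·n_exp); draw the direct effect
    alpha_j ~ N(pleiotropy_mean, pleiotropy_sd²); set the outcome effect to
    theta·beta_x + alpha_j + noise with noise SD equal to the outcome se.
    The returned truth record stores theta and every alpha_j.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=k)
    het = 2.0 * maf * (1.0 - maf)
    beta_x = np.sqrt(cfg.h2_per_snp / het)
    se_x = 1.0 / np.sqrt(het * cfg.n_exp)
    se_y = 1.0 / np.sqrt(het * cfg.n_out)
    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k)
    beta_y = cfg.theta * beta_x + alpha + rng.normal(0.0, se_y)

    rsid = np.array([f"rs{j + 1:06d}" for j in range(k)])
    pos = 1 + np.arange(k) * 1_000_000
    chrom = np.repeat("1", k)
    exposure = _make_table(
        "sim-exposure", rsid, chrom, pos, beta_x, se_x,
        _two_sided_p(beta_x / se_x), maf, cfg.n_exp, cfg.n_exp // 2,
    )
    outcome = _make_table(
        "sim-outcome", rsid, chrom, pos, beta_y, se_y,
        _two_sided_p(beta_y / se_y), maf, cfg.n_out, cfg.n_out // 2,
    )
    truth = {
        "theta": cfg.theta,
        "alpha": alpha.tolist(),
        "maf": maf.tolist(),
        "beta_x_true": beta_x.tolist(),
        "seed": cfg.seed,
    }
    return exposure, outcome, truth


def _ld_matrix(q: int, ld_decay: float) -> np.ndarray:
    idx = np.arange(q)
    return np.exp(-ld_decay * np.abs(idx[:, None] - idx[None, :]))


def _causal_indices(cfg: ColocSimConfig) -> tuple[int | None, int | None]:
    q = cfg.n_snps
    mid = q // 2
    if cfg.scenario == "H0":
        return None, None
    if cfg.scenario == "H1":
        return mid, None
    if cfg.scenario == "H2":
        return None, mid
    if cfg.scenario == "H3":
        return q // 4, (3 * q) // 4 if q >= 4 else q - 1
    return mid, mid  # H4


def simulate_coloc_region(
    cfg: ColocSimConfig,
) -> tuple[SumStatsTable, SumStatsTable, dict]:
    """Simulate regional summary statistics for two traits over shared LD.

    Z-scores for each trait are drawn from MVN(R·lambda, R) where R is the
    exponential-decay LD matrix and lambda puts the scenario's non-centrality
    on the causal index (or indices).  Betas and standard errors consistent
    with z and the sample size are emitted for each trait.
    """
    q = cfg.n_snps
    rng = np.random.default_rng(cfg.seed)
    r_mat = _ld_matrix(q, cfg.ld_decay)
    try:
        chol = np.linalg.cholesky(r_mat + 1e-10 * np.eye(q))
    except np.linalg.LinAlgError as err:
        raise ValidationError(
            "LD matrix is not positive definite even after jitter"
        ) from err

    c1, c2 = _causal_indices(cfg)
    lam1 = np.zeros(q)
    lam2 = np.zeros(q)
    if c1 is not None:
        lam1[c1] = cfg.effect_size_1
    if c2 is not None:
        lam2[c2] = cfg.effect_size_2
    z1 = r_mat @ lam1 + chol @ rng.standard_normal(q)
    z2 = r_mat @ lam2 + chol @ rng.standard_normal(q)

    maf = rng.uniform(*cfg.maf_range, size=q)
    het = 2.0 * maf * (1.0 - maf)
    se1 = 1.0 / np.sqrt(het * cfg.n_1)
    se2 = 1.0 / np.sqrt(het * cfg.n_2)

    rsid = np.array([f"rs{j + 1:06d}" for j in range(q)])
    pos = np.linspace(
        cfg.center_pos - cfg.half_width_bp, cfg.center_pos + cfg.half_width_bp, q
    ).astype(int)
    chrom = np.repeat(cfg.chrom, q)
    t1 = _make_table(
        "sim-trait1", rsid, chrom, pos, z1 * se1, se1,
        _two_sided_p(z1), maf, cfg.n_1, cfg.n_1 // 2,
    )
    t2 = _make_table(
        "sim-trait2", rsid, chrom, pos, z2 * se2, se2,
        _two_sided_p(z2), maf, cfg.n_2, cfg.n_2 // 2,
    )
    truth = {
        "scenario": cfg.scenario,
        "causal_index_1": c1,
        "causal_index_2": c2,
        "causal_rsid_1": rsid[c1] if c1 is not None else None,
        "causal_rsid_2": rsid[c2] if c2 is not None else None,
        "seed": cfg.seed,
    }
    return t1, t2, truth


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a genes-by-samples expression matrix with group mean shifts.

    Entries are Normal(shift_g·group, noise_sd²); labels are 1 for cases and 0
    for controls.  Gene names come from ``effect_genes`` first, padded with
    ``gene<k>`` up to ``n_genes``.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.effect_genes)[: cfg.n_genes]
    names += [f"gene{k + 1}" for k in range(len(names), cfg.n_genes)]
    shifts = np.array([cfg.effect_genes.get(g, 0.0) for g in names])

    n = cfg.n_cases + cfg.n_controls
    labels = np.concatenate([np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)])
    x = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    x += cfg.noise_sd * shifts[:, None] * labels[None, :]
    samples = [
        f"case{j + 1}" if labels[j] else f"ctrl{j - cfg.n_cases + 1}" for j in range(n)
    ]
    return pd.DataFrame(x, index=names, columns=samples), labels
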
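"""Bayesian colocalization of two traits via per-SNP approximate Bayes factors.

For each SNP the evidence of association with a trait is the Wakefield
approximate Bayes factor, computed from the variance of the effect estimate
V, the z-score, and a prior effect variance W through the shrinkage ratio
r = W/(V + W):

    lABF = 0.5 · (log(1 − r) + r·z²)

Combining both traits' per-SNP lABFs with priors p1, p2 (either trait causal
at a given SNP) and p12 (both causal at the same SNP) yields posterior
probabilities over five regional hypotheses: H0 no association, H1/H2 one
trait only, H3 two distinct causal variants, H4 one shared causal variant.
The per-SNP posterior for the shared variant (SNP.PP.H4) attributes H4 to
individual SNPs.  All sums over SNPs run in log space (logsumexp), so lABFs
in the thousands are handled without overflow.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats_io import SumStatsTable, ValidationError

logger = logging.getLogger("mrdietcvd")

__all__ = [
    "ColocTrait", "ColocResult", "compute_labf", "prior_variance",
    "coloc_posteriors", "extract_region", "trait_from_sumstats",
    "DEFAULT_PRIORS",
]

#: Conventional single-variant priors: per-SNP probability of association
#: with trait 1 only, trait 2 only, and both.
DEFAULT_PRIORS: dict[str, float] = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}


@dataclass
class ColocTrait:
    """Per-SNP association summary for one trait over a region.

    ``snps`` columns: rsid, beta, V (variance of beta), z (= beta/sqrt(V)),
    maf, n, case_fraction.  ``sdY`` (quantitative traits) may be supplied or
    estimated from V, maf, and n.
    """

    trait_id: str
    trait_type: str
    snps: pd.DataFrame
    sdY: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValidationError(f"trait_type {self.trait_type!r} unknown")
        v = self.snps["V"].to_numpy(float)
        if (v <= 0).any():
            raise ValidationError("V must be > 0 for every SNP")
        z = self.snps["z"].to_numpy(float)
        beta = self.snps["beta"].to_numpy(float)
        err = np.abs(z - beta / np.sqrt(v)) / np.maximum(np.abs(z), 1.0)
        if (err > 1e-6).any():
            raise ValidationError("z inconsistent with beta and V (rel. tol 1e-6)")


@dataclass
class ColocResult:
    """Posterior colocalization summary over a region of Q SNPs."""

    n_snps: int
    labf_1: np.ndarray
    labf_2: np.ndarray
    internal_sum_labf: np.ndarray
    pp: dict[str, float]
    snp_pp_h4: np.ndarray
    priors: dict[str, float]
    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    coloc_id: str = ""

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"posterior probabilities sum to {total}, not 1")


def compute_labf(z: float | np.ndarray, V: float | np.ndarray, W: float):
    """Log approximate Bayes factor and shrinkage ratio for one SNP.

    r = W/(V + W); lABF = 0.5·(log(1 − r) + r·z²).  Returns ``(labf, r)``;
    accepts scalars or arrays.
    """
    V = np.asarray(V, float)
    if np.any(V <= 0):
        raise ValidationError("V must be > 0")
    if not W > 0:
        raise ValidationError("prior effect variance W must be > 0")
    r = W / (V + W)
    labf = 0.5 * (np.log1p(-r) + r * np.square(z))
    if np.ndim(labf) == 0:
        return float(labf), float(r)
    return labf, r


def _estimate_sdy(v: np.ndarray, maf: np.ndarray, n: np.ndarray) -> float:
    """Estimate the trait SD by regressing 2·maf·(1−maf)·n on 1/V through 0."""
    oneover = 1.0 / v
    nvx = 2.0 * n * maf * (1.0 - maf)
    slope = float((oneover * nvx).sum() / (oneover**2).sum())
    if slope <= 0:
        raise ValidationError("sdY estimation produced a non-positive variance")
    return math.sqrt(slope)


def prior_variance(trait: ColocTrait) -> float:
    """Prior variance W of the causal effect for one trait.

    Case/control traits use W = 0.2² on the log-odds scale; quantitative
    traits use W = (0.15·sdY)², estimating sdY from (V, maf, n) when absent.
    """
    if trait.trait_type == "case_control":
        return 0.2**2
    sdy = trait.sdY
    if sdy is None:
        cols = trait.snps
        maf = cols.get("maf")
        n = cols.get("n")
        if maf is None or n is None or maf.isna().any() or n.isna().any():
            raise ValidationError(
                f"quantitative trait {trait.trait_id!r}: supply sdY or per-SNP "
                "maf and n so it can be estimated"
            )
        sdy = _estimate_sdy(
            cols["V"].to_numpy(float), maf.to_numpy(float), n.to_numpy(float)
        )
        logger.info("estimated sdY = %.4g for %s", sdy, trait.trait_id)
    return (0.15 * sdy) ** 2


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) − exp(b)); clamps to −inf with a warning when b >= a."""
    if b >= a:
        warnings.warn(
            "logdiff: sum of single-trait evidence does not exceed the joint "
            "term (rounding); clamping H3 weight to zero", stacklevel=2,
        )
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_posteriors(
    t1: ColocTrait,
    t2: ColocTrait,
    priors: dict[str, float] | None = None,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Both traits must cover the same rsids in the same order.  With
    L1 = logsumexp(lABF₁), L2 = logsumexp(lABF₂), L12 = logsumexp(lABF₁+lABF₂),
    the unnormalized log-weights are::

        H0: 0                  H1: log p1 + L1        H2: log p2 + L2
        H3: log p1 + log p2 + logdiff(L1 + L2, L12)
        H4: log p12 + L12

    and ``snp_pp_h4[j] = exp(lABF₁ⱼ + lABF₂ⱼ − L12)``.
    """
    pri = dict(DEFAULT_PRIORS)
    if priors:
        pri.update(priors)
    rs1 = list(t1.snps["rsid"])
    rs2 = list(t2.snps["rsid"])
    if rs1 != rs2:
        diff = sorted(set(rs1) ^ set(rs2))
        raise ValidationError(
            f"traits cover different rsids (symmetric difference: {diff[:10]}"
            f"{'...' if len(diff) > 10 else ''})"
        )
    q = len(rs1)
    if q < 1:
        raise ValidationError("empty region")

    w1 = prior_variance(t1)
    w2 = prior_variance(t2)
    labf1, r1 = compute_labf(t1.snps["z"].to_numpy(float), t1.snps["V"].to_numpy(float), w1)
    labf2, r2 = compute_labf(t2.snps["z"].to_numpy(float), t2.snps["V"].to_numpy(float), w2)
    labf1 = np.atleast_1d(labf1)
    labf2 = np.atleast_1d(labf2)
    r1 = np.atleast_1d(r1)
    r2 = np.atleast_1d(r2)
    joint = labf1 + labf2
    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l12 = float(logsumexp(joint))

    lw = np.array([
        0.0,
        math.log(pri["p1"]) + l1,
        math.log(pri["p2"]) + l2,
        (math.log(pri["p1"]) + math.log(pri["p2"]) + _logdiff(l1 + l2, l12))
        if q > 1 else -np.inf,
        math.log(pri["p12"]) + l12,
    ])
    pp_vec = np.exp(lw - logsumexp(lw))
    pp_vec /= pp_vec.sum()
    pp = dict(zip(("H0", "H1", "H2", "H3", "H4"), pp_vec.tolist()))
    snp_pp_h4 = np.exp(joint - l12)
    snp_pp_h4 /= snp_pp_h4.sum()

    snp_table = pd.DataFrame({
        "SNP": rs1,
        "V.df1": t1.snps["V"].to_numpy(float),
        "z.df1": t1.snps["z"].to_numpy(float),
        "r.df1": r1,
        "lABF.df1": labf1,
        "V.df2": t2.snps["V"].to_numpy(float),
        "z.df2": t2.snps["z"].to_numpy(float),
        "r.df2": r2,
        "lABF.df2": labf2,
        "internal.sum.lABF": joint,
        "SNP.PP.H4": snp_pp_h4,
    })
    return ColocResult(
        n_snps=q, labf_1=labf1, labf_2=labf2, internal_sum_labf=joint,
        pp=pp, snp_pp_h4=snp_pp_h4, priors=pri, snp_table=snp_table,
        coloc_id=f"{t1.trait_id};{t2.trait_id}" if t1.trait_id or t2.trait_id else "",
    )


def extract_region(
    table: SumStatsTable,
    chrom: str,
    pos: int,
    half_width_bp: int = 500_000,
) -> SumStatsTable:
    """Rows on ``chrom`` within the closed window [pos − hw, pos + hw]."""
    kept = [
        r for r in table
        if r.pos is not None
        and str(r.chrom) == str(chrom)
        and abs(r.pos - pos) <= half_width_bp
    ]
    if not kept:
        raise ValidationError(
            f"no SNPs of {table.trait_id!r} in {chrom}:"
            f"{pos - half_width_bp}-{pos + half_width_bp}"
        )
    return SumStatsTable(
        trait_id=table.trait_id, records=kept, provenance=table.provenance
    )


def trait_from_sumstats(
    table: SumStatsTable,
    trait_type: str | None = None,
    sdY: float | None = None,
) -> ColocTrait:
    """Build a :class:`ColocTrait` from a summary-statistics table."""
    df = table.to_frame()
    tt = trait_type or (table.records[0].trait_type if len(table) else "case_control")
    v = df["se"].to_numpy(float) ** 2
    beta = df["beta"].to_numpy(float)
    eaf = df["eaf"].to_numpy(float)
    maf = np.where(eaf < 0.5, eaf, 1.0 - eaf)
    case_frac = df["n_case"].to_numpy(float) / df["n"].to_numpy(float)
    snps = pd.DataFrame({
        "rsid": df["rsid"],
        "beta": beta,
        "V": v,
        "z": beta / np.sqrt(v),
        "maf": maf,
        "n": df["n"].to_numpy(float),
        "case_fraction": case_frac,
    })
    return ColocTrait(trait_id=table.trait_id, trait_type=tt, snps=snps, sdY=sdY)
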
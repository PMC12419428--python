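"""Heterogeneity, pleiotropy, directionality, influence, and FDR procedures.

The sensitivity battery run after each exposure/outcome MR fit: Cochran's Q
over the per-SNP Wald ratios (with the I² restatement), the MR-Egger
intercept test (surfaced from the estimator module — single source of
truth), the Steiger directionality check (instruments should explain more
variance in the exposure than in the outcome), leave-one-out influence
analysis, and grouped Benjamini–Hochberg adjustment for the report's FDR
column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .instruments import HarmonizedSet
from .mr_estimators import egger, ivw, wald_ratios
from .sumstats_io import ValidationError

__all__ = [
    "SensitivityReport", "cochran_q", "steiger_direction", "leave_one_out",
    "bh_adjust", "sensitivity_report",
]


@dataclass
class SensitivityReport:
    """Per exposure/outcome-pair sensitivity summary."""

    q_stat: float
    q_df: int
    q_pval: float
    i2: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    steiger_direction: bool
    steiger_pval: float
    loo: pd.DataFrame
    influential: list[str]


def cochran_q(ratios: pd.DataFrame) -> tuple[float, int, float, float]:
    """Cochran's Q over per-SNP ratios: Q = Σ wⱼ (ratioⱼ − β_IVW)².

    Returns ``(q_stat, q_df, q_pval, i2)`` with the upper-tail chi-square
    p-value on k−1 degrees of freedom and I² = max(0, (Q − df)/Q).
    """
    r = np.asarray(ratios["ratio"], float)
    se = np.asarray(ratios["ratio_se"], float)
    k = len(r)
    if k < 2:
        raise ValidationError(f"Cochran's Q needs >= 2 ratios, got {k}")
    w = 1.0 / se**2
    beta = (w * r).sum() / w.sum()
    q = float((w * (r - beta) ** 2).sum())
    df = k - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, pval, i2


def steiger_direction(h: HarmonizedSet) -> tuple[bool, float]:
    """Test that instruments explain more exposure than outcome variance.

    Per SNP, r² with each trait is z²/(z² + n); the direction flag is
    Σ r²_x > Σ r²_y (strict, so exact ties report FALSE), and the p-value is
    a two-sided normal test on the difference of the Fisher-z-transformed
    pooled correlations with variances 1/(n − 3).
    """
    nx = h.pairs["n_x"].to_numpy(float)
    ny = h.pairs["n_y"].to_numpy(float)
    if np.isnan(nx).any() or np.isnan(ny).any():
        raise ValidationError(
            "Steiger test needs per-SNP sample sizes on both sides; supply the "
            "'n' column in both summary-statistics files (or via column_map)"
        )
    zx = h.pairs["beta_x"].to_numpy(float) / h.pairs["se_x"].to_numpy(float)
    zy = h.pairs["beta_y"].to_numpy(float) / h.pairs["se_y"].to_numpy(float)
    r2x = zx**2 / (zx**2 + nx)
    r2y = zy**2 / (zy**2 + ny)
    sum_x, sum_y = float(r2x.sum()), float(r2y.sum())
    direction = sum_x > sum_y
    rx = np.sqrt(min(sum_x, 1.0 - 1e-12))
    ry = np.sqrt(min(sum_y, 1.0 - 1e-12))
    var = 1.0 / (nx.mean() - 3.0) + 1.0 / (ny.mean() - 3.0)
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(var)
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return direction, pval


def leave_one_out(
    h: HarmonizedSet, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """k IVW re-fits, each omitting one SNP; flags influential instruments.

    A SNP is influential when its omission flips the sign of the estimate or
    moves the p-value across ``alpha`` relative to the full-set IVW fit.
    """
    k = h.nsnp
    if k < 3:
        raise ValidationError(f"leave-one-out needs >= 3 SNPs, got {k}")
    full = ivw(h, effects_model="fixed")
    rows, influential = [], []
    for i in range(k):
        keep = np.array([j for j in range(k) if j != i])
        est = ivw(h.subset(keep), effects_model="fixed")
        rsid = h.pairs["rsid"].iloc[i]
        rows.append({
            "rsid": rsid, "beta": est.beta, "se": est.se, "pval": est.pval,
        })
        sign_flip = np.sign(est.beta) != np.sign(full.beta)
        crosses = (est.pval < alpha) != (full.pval < alpha)
        if sign_flip or crosses:
            influential.append(rsid)
    return pd.DataFrame(rows), influential


def bh_adjust(
    pvals, grouping=None
) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, applied within each group.

    ``grouping`` is an optional label per test (e.g. the outcome dataset the
    test belongs to); adjustment runs independently within each label and
    the input order is restored.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValidationError("bh_adjust: empty p-value collection")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    if grouping is None:
        grouping = np.zeros(p.size)
    labels = np.asarray(grouping)
    if labels.size != p.size:
        raise ValidationError("grouping length does not match p-values")
    out = np.empty_like(p)
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def sensitivity_report(h: HarmonizedSet, alpha: float = 0.05) -> SensitivityReport:
    """Assemble the full battery for one harmonized exposure/outcome pair."""
    wr = wald_ratios(h)
    q, df, q_p, i2 = cochran_q(wr)
    if h.nsnp >= 3:
        eg = egger(h)
        e_int = eg.extra["intercept"]
        e_se = eg.extra["intercept_se"]
        e_p = eg.extra["intercept_p"]
        loo, influential = leave_one_out(h, alpha=alpha)
    else:
        e_int = e_se = e_p = None
        loo, influential = pd.DataFrame(columns=["rsid", "beta", "se", "pval"]), []
    direction, steiger_p = steiger_direction(h)
    return SensitivityReport(
        q_stat=q, q_df=df, q_pval=q_p, i2=i2,
        egger_intercept=e_int, egger_intercept_se=e_se, egger_intercept_p=e_p,
        steiger_direction=direction, steiger_pval=steiger_p,
        loo=loo, influential=influential,
    )
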
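"""Pooling per-outcome MR estimates within disease groups.

Each disease (heart failure, coronary heart disease, myocardial infarction,
...) is represented by several outcome GWAS datasets; the per-dataset IVW
odds ratios are converted back to log-OR / SE from their printed 95%
confidence intervals and pooled on the log scale: fixed-effect inverse
variance, and DerSimonian–Laird random effects with the moment estimator of
the between-study variance τ².  The Cochran-Q heterogeneity p-value of the
pooled studies is surfaced as the report's sensitivity column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .sumstats_io import Z95, MrReportRow, ValidationError

__all__ = [
    "StudyEffect", "MetaResult", "ci_to_logse",
    "pool_fixed", "pool_random_dl", "meta_group",
]


@dataclass
class StudyEffect:
    """One study's effect on the log-odds scale."""

    study_id: str
    log_or: float
    se: float
    source: str = "direct"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(
                f"study {self.study_id!r}: se must be > 0, got {self.se}"
            )


@dataclass
class MetaResult:
    """Pooled fixed/random estimates with heterogeneity for one group."""

    group: str
    exposure_id: str
    k_studies: int
    fixed_or: float
    fixed_lci: float
    fixed_uci: float
    fixed_p: float
    random_or: float
    random_lci: float
    random_uci: float
    random_p: float
    q_stat: float
    q_pval: float
    tau2: float
    i2: float
    sensitivity_p: float


def ci_to_logse(
    or_: float, lci: float, uci: float, level: float = 0.95, study_id: str = ""
) -> StudyEffect:
    """Recover log-OR and its SE from an odds ratio and confidence interval.

    se = (ln(uci) − ln(lci)) / (2·z) with z the two-sided critical value at
    ``level`` (1.959964 at 95%).  Degenerate intervals (uci = lci) and
    ordering violations raise a :class:`ValidationError`.
    """
    if not (0 < lci <= or_ <= uci):
        raise ValidationError(
            f"study {study_id!r}: CI ordering violated: "
            f"need 0 < {lci} <= {or_} <= {uci}"
        )
    z = Z95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    se = (math.log(uci) - math.log(lci)) / (2.0 * z)
    if se <= 0:
        raise ValidationError(f"study {study_id!r}: degenerate CI gives se = 0")
    return StudyEffect(study_id=study_id, log_or=math.log(or_), se=se, source="from_ci")


def pool_fixed(effects: Sequence[StudyEffect]) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance pooling; returns (est, se, p) on log scale."""
    if len(effects) < 1:
        raise ValidationError("pool_fixed needs at least one study")
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    est = float((w * y).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    p = float(2.0 * stats.norm.sf(abs(est) / se))
    return est, se, p


def pool_random_dl(
    effects: Sequence[StudyEffect],
) -> tuple[float, float, float, float, float, float, float]:
    """DerSimonian–Laird random-effects pooling.

    Q = Σ wᵢ (yᵢ − est_fixed)², C = Σw − Σw²/Σw,
    τ² = max(0, (Q − (k−1))/C); studies are re-weighted 1/(seᵢ² + τ²).
    Returns (est, se, p, tau2, q_stat, q_pval, i2) on the log scale.
    """
    k = len(effects)
    if k < 2:
        raise ValidationError("pool_random_dl needs >= 2 studies; use pool_fixed")
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    est_fixed = (w * y).sum() / w.sum()
    q = float((w * (y - est_fixed) ** 2).sum())
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in effects]) + tau2)
    est = float((w_star * y).sum() / w_star.sum())
    se = float(np.sqrt(1.0 / w_star.sum()))
    p = float(2.0 * stats.norm.sf(abs(est) / se))
    q_pval = float(stats.chi2.sf(q, k - 1))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return est, se, p, tau2, q, q_pval, i2


def _is_ivw(method: str) -> bool:
    m = method.strip().lower()
    return m.startswith("ivw") or m == "inverse variance weighted"


def meta_group(
    table1: Iterable[MrReportRow],
    grouping: Mapping[str, Sequence[str]],
) -> list[MetaResult]:
    """Pool the per-study IVW rows of the MR report within disease groups.

    ``grouping`` maps each disease label to its outcome GWAS ids; every
    outcome_id appearing in ``table1`` must be mapped to exactly one disease.
    Per (disease, exposure) the studies' OR/CI are converted via
    :func:`ci_to_logse` and pooled fixed and random; the heterogeneity
    p-value is surfaced as ``sensitivity_p``.  Output is ordered by
    (disease, exposure).
    """
    outcome_to_disease: dict[str, str] = {}
    for disease, ids in grouping.items():
        for oid in ids:
            if oid in outcome_to_disease:
                raise ValidationError(
                    f"outcome_id {oid!r} mapped to both "
                    f"{outcome_to_disease[oid]!r} and {disease!r}"
                )
            outcome_to_disease[oid] = disease

    rows = [r for r in table1 if _is_ivw(r.method)]
    unmapped = sorted({r.outcome_id for r in rows} - set(outcome_to_disease))
    if unmapped:
        raise ValidationError(f"outcome_id(s) not mapped to a disease: {unmapped}")

    cells: dict[tuple[str, str], list[MrReportRow]] = {}
    for r in rows:
        cells.setdefault((outcome_to_disease[r.outcome_id], r.exposure_id), []).append(r)

    out: list[MetaResult] = []
    for (disease, exposure_id) in sorted(cells):
        studies = [
            ci_to_logse(r.or_, r.or_lci95, r.or_uci95, study_id=r.outcome_id)
            for r in cells[(disease, exposure_id)]
        ]
        f_est, f_se, f_p = pool_fixed(studies)
        if len(studies) >= 2:
            r_est, r_se, r_p, tau2, q, q_p, i2 = pool_random_dl(studies)
        else:
            r_est, r_se, r_p = f_est, f_se, f_p
            tau2, q, q_p, i2 = 0.0, 0.0, 1.0, 0.0
        out.append(MetaResult(
            group=disease, exposure_id=exposure_id, k_studies=len(studies),
            fixed_or=math.exp(f_est),
            fixed_lci=math.exp(f_est - Z95 * f_se),
            fixed_uci=math.exp(f_est + Z95 * f_se),
            fixed_p=f_p,
            random_or=math.exp(r_est),
            random_lci=math.exp(r_est - Z95 * r_se),
            random_uci=math.exp(r_est + Z95 * r_se),
            random_p=r_p,
            q_stat=q, q_pval=q_p, tau2=tau2, i2=i2,
            sensitivity_p=q_p,
        ))
    return out
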
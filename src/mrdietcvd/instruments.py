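"""Instrument selection, LD clumping, and exposure/outcome harmonization.

Instruments are SNPs strongly associated with the exposure (default
p < 5e-6), pruned to approximate linkage equilibrium (r² < 0.001 within a
10,000 kb window), with variants linked to known confounders removed via a
user-supplied exclusion list (a desk-scale stand-in for PhenoScanner
lookups).  Harmonization aligns exposure and outcome effects to a common
effect allele, resolving swapped and strand-flipped records and dropping
ambiguous palindromic SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import (
    SnpAssociation,
    SumStatsTable,
    ValidationError,
    MrDietCvdError,
)

logger = logging.getLogger("mrdietcvd")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "rsid", "effect_allele", "other_allele",
    "beta_x", "se_x", "beta_y", "se_y",
    "eaf_x", "eaf_y", "pval_x", "n_x", "n_y",
]


class EmptyInstrumentsError(MrDietCvdError):
    """No SNPs survive instrument selection or harmonization."""


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``pairs`` is a DataFrame with one row per kept SNP (columns
    ``PAIR_COLUMNS``); ``removed`` records each dropped rsid with its reason
    (``palindromic`` or ``allele_mismatch``).
    """

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame
    removed: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValidationError(f"HarmonizedSet pairs missing columns {missing}")
        kept = set(self.pairs["rsid"])
        dropped = {r for r, _ in self.removed}
        both = kept & dropped
        if both:
            raise ValidationError(f"rsids both kept and removed: {sorted(both)}")
        if len(self.pairs) and (
            (self.pairs["se_x"] <= 0).any() or (self.pairs["se_y"] <= 0).any()
        ):
            raise ValidationError("harmonized pairs contain non-positive se")

    @property
    def nsnp(self) -> int:
        return len(self.pairs)

    def subset(self, keep: np.ndarray) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_id, self.outcome_id,
            self.pairs.iloc[keep].reset_index(drop=True), list(self.removed),
        )


def select_instruments(
    exposure: SumStatsTable,
    p_threshold: float = 5e-6,
    exclusion_list: set[str] | frozenset[str] = frozenset(),
) -> SumStatsTable:
    """Keep genome-wide-suggestive SNPs not linked to known confounders.

    Keeps rows with ``pval < p_threshold`` whose rsid is not on the exclusion
    list, preserving input order.  Raises :class:`EmptyInstrumentsError` naming
    both filters' attrition when nothing survives.
    """
    if not (0 < p_threshold < 1):
        raise ValidationError(f"p_threshold {p_threshold} not in (0, 1)")
    sig = [r for r in exposure if r.pval < p_threshold]
    kept = [r for r in sig if r.rsid not in exclusion_list]
    n_excl = len(sig) - len(kept)
    logger.info(
        "select_instruments[%s]: %d input, %d pass p<%g, %d after confounder "
        "exclusion (%d removed)",
        exposure.trait_id, len(exposure), len(sig), p_threshold, len(kept), n_excl,
    )
    if not kept:
        raise EmptyInstrumentsError(
            f"no instruments for {exposure.trait_id!r}: "
            f"{len(exposure) - len(sig)} of {len(exposure)} failed p < {p_threshold}, "
            f"{n_excl} removed as confounder-linked"
        )
    return SumStatsTable(
        trait_id=exposure.trait_id, records=kept, provenance=exposure.provenance
    )


def ld_clump(
    candidates: SumStatsTable,
    ld: pd.DataFrame | np.ndarray | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> SumStatsTable:
    """Greedy LD clumping on a provided r² matrix.

    Candidates are visited by ascending p-value (ties broken by chromosome,
    position, then rsid, so output is independent of input row order); a SNP
    is accepted iff its r² with every already-accepted SNP within
    ``window_kb`` on the same chromosome is below ``r2_threshold``.
    ``ld=None`` treats all candidates as unlinked.
    """
    rsids = candidates.rsids()
    k = len(rsids)
    if ld is None:
        r2 = np.eye(k)
    elif isinstance(ld, pd.DataFrame):
        missing = [r for r in rsids if r not in ld.index]
        if missing:
            raise ValidationError(f"LD matrix missing candidates: {missing}")
        r2 = ld.loc[rsids, rsids].to_numpy(float)
    else:
        r2 = np.asarray(ld, float)
        if r2.shape != (k, k):
            raise ValidationError(
                f"LD matrix shape {r2.shape} does not match {k} candidates"
            )
    if not np.allclose(r2, r2.T, atol=1e-8) or not np.allclose(np.diag(r2), 1.0):
        raise ValidationError("LD matrix must be symmetric with unit diagonal")
    if (r2 < -1e-12).any() or (r2 > 1 + 1e-12).any():
        raise ValidationError("LD r² entries must lie in [0, 1]")

    def sort_key(i: int):
        r = candidates.records[i]
        return (r.pval, str(r.chrom), r.pos if r.pos is not None else 0, r.rsid)

    order = sorted(range(k), key=sort_key)
    accepted: list[int] = []
    window_bp = window_kb * 1000.0
    for i in order:
        ri = candidates.records[i]
        ok = True
        for j in accepted:
            rj = candidates.records[j]
            same_chrom = str(ri.chrom) == str(rj.chrom)
            in_window = (
                same_chrom
                and ri.pos is not None
                and rj.pos is not None
                and abs(ri.pos - rj.pos) <= window_bp
            )
            if in_window and r2[i, j] >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
    keep = set(accepted)
    kept = [r for i, r in enumerate(candidates.records) if i in keep]
    logger.info(
        "ld_clump[%s]: %d candidates -> %d index SNPs (r2<%g, window %g kb)",
        candidates.trait_id, k, len(kept), r2_threshold, window_kb,
    )
    return SumStatsTable(
        trait_id=candidates.trait_id, records=kept, provenance=candidates.provenance
    )


def _complemented(a1: str, a2: str) -> tuple[str, str]:
    return _COMPLEMENT[a1], _COMPLEMENT[a2]


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindromic_eaf_limit: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    Inner-join on rsid.  Swapped outcome alleles negate ``beta_y`` and flip
    ``eaf_y``; strand-complemented alleles are complemented then aligned.
    Palindromic SNPs (A/T or C/G) are kept only when both allele frequencies
    lie outside the ambiguity band ``[limit, 1−limit]`` and point the same way;
    otherwise they are removed with reason ``palindromic``.  Irreconcilable
    allele sets are removed with reason ``allele_mismatch``.
    """
    out_by_rsid = {r.rsid: r for r in outcome}
    shared = [r for r in exposure if r.rsid in out_by_rsid]
    if not shared:
        raise EmptyInstrumentsError(
            f"no shared rsids between {exposure.trait_id!r} ({len(exposure)} SNPs) "
            f"and {outcome.trait_id!r} ({len(outcome)} SNPs)"
        )
    lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit

    rows = []
    removed: list[tuple[str, str]] = []
    for ex in shared:
        oc = out_by_rsid[ex.rsid]
        ea, oa = oc.effect_allele, oc.other_allele
        beta_y, eaf_y = oc.beta, oc.eaf

        if ex.is_palindromic:
            # Strand is unresolvable from alleles alone; use frequencies.
            if {ea, oa} != {ex.effect_allele, ex.other_allele}:
                removed.append((ex.rsid, "allele_mismatch"))
                continue
            if ex.eaf is None or eaf_y is None:
                removed.append((ex.rsid, "palindromic"))
                continue
            ambiguous = (lo <= ex.eaf <= hi) or (lo <= eaf_y <= hi)
            if ea == ex.effect_allele:
                agree = (ex.eaf < 0.5) == (eaf_y < 0.5)
            else:  # swapped labels: frequencies should be complementary
                agree = (ex.eaf < 0.5) == (eaf_y > 0.5)
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            if ambiguous or not agree:
                removed.append((ex.rsid, "palindromic"))
                continue
        else:
            if (ea, oa) == (ex.effect_allele, ex.other_allele):
                pass
            elif (oa, ea) == (ex.effect_allele, ex.other_allele):
                beta_y = -beta_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            elif _complemented(ea, oa) == (ex.effect_allele, ex.other_allele):
                pass  # strand flip, same orientation
            elif _complemented(oa, ea) == (ex.effect_allele, ex.other_allele):
                beta_y = -beta_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            else:
                removed.append((ex.rsid, "allele_mismatch"))
                continue

        rows.append({
            "rsid": ex.rsid,
            "effect_allele": ex.effect_allele,
            "other_allele": ex.other_allele,
            "beta_x": ex.beta, "se_x": ex.se,
            "beta_y": beta_y, "se_y": oc.se,
            "eaf_x": ex.eaf, "eaf_y": eaf_y,
            "pval_x": ex.pval,
            "n_x": ex.n, "n_y": oc.n,
        })

    if not rows:
        raise EmptyInstrumentsError(
            f"all {len(shared)} shared SNPs removed during harmonization "
            f"({exposure.trait_id!r} vs {outcome.trait_id!r}): "
            + ", ".join(f"{r}:{why}" for r, why in removed)
        )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    logger.info(
        "harmonize[%s vs %s]: %d shared, %d kept, %d removed",
        exposure.trait_id, outcome.trait_id, len(shared), len(pairs), len(removed),
    )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        pairs=pairs,
        removed=removed,
    )
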
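"""Domain types, validation, and readers/writers for GWAS summary statistics.

The whole pipeline works on *summary-level* GWAS data: one row per SNP with the
per-allele effect (``beta``, log-odds for binary traits), its standard error,
the association p-value, the effect-allele frequency, and sample sizes.  This
module defines the validated in-memory containers and the tab-separated text
formats used for inputs and for the three report layouts (per-method MR
estimates, pooled meta-analysis results, and per-SNP colocalization output).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrdietcvd")

#: 1.959964 rather than scipy's 1.95996398... so that exponentiated CIs
#: round-trip against three-decimal rendered tables.
Z95 = 1.959964

#: p-values printed as exactly 0 by upstream GWAS pipelines are floored here.
P_FLOOR = 1e-300

_VALID_ALLELES = {"A", "C", "G", "T"}

MANDATORY_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "n", "n_case")


class MrDietCvdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrDietCvdError):
    """Bad configuration: missing columns, unknown layout, invalid thresholds."""


class ValidationError(MrDietCvdError):
    """Input data violates a stated invariant."""


class PipelineError(MrDietCvdError):
    """A pipeline stage failed; message names the stage and the offending pair."""


@dataclass
class SnpAssociation:
    """One SNP's summary statistics for one trait.

    ``beta`` is the per-effect-allele effect on the trait (log-odds scale for
    case/control traits).  ``eaf``, ``n`` and ``n_case`` are optional but
    required by some downstream operations (palindromic-SNP inference, Steiger
    directionality, sdY estimation), which raise informative errors when they
    are missing.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    trait_id: str = ""
    trait_type: str = "case_control"

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.pval == 0:
            warnings.warn(
                f"{self.rsid}: p-value of 0 floored to {P_FLOOR}", stacklevel=2
            )
            self.pval = P_FLOOR
        problems = self.problems()
        if problems:
            raise ValidationError(f"{self.rsid}: " + "; ".join(problems))

    def problems(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        out = []
        if self.effect_allele not in _VALID_ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            out.append(f"other_allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect and other allele are identical")
        if not np.isfinite(self.beta):
            out.append(f"beta {self.beta} is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append(f"se {self.se} is not > 0")
        if not (0 < self.pval <= 1):
            out.append(f"pval {self.pval} is outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            out.append(f"eaf {self.eaf} is outside [0, 1]")
        if self.n is not None and self.n < 1:
            out.append(f"n {self.n} is < 1")
        if self.n_case is not None and self.n is not None and self.n_case > self.n:
            out.append(f"n_case {self.n_case} exceeds n {self.n}")
        if self.trait_type not in ("quantitative", "case_control"):
            out.append(f"trait_type {self.trait_type!r} unknown")
        return out

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SumStatsTable:
    """An ordered collection of :class:`SnpAssociation` for one trait."""

    trait_id: str
    records: list[SnpAssociation]
    provenance: str = ""

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        seen: set[str] = set()
        for rsid in rsids:
            if rsid in seen:
                raise ValidationError(f"duplicate rsid {rsid!r} in table {self.trait_id!r}")
            seen.add(rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        cols = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
        return pd.DataFrame({c: [getattr(r, c) for r in self.records] for c in cols})

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        trait_id: str = "",
        trait_type: str = "case_control",
        provenance: str = "",
    ) -> "SumStatsTable":
        records, problems = [], []
        for idx, row in df.iterrows():
            kwargs = {c: row[c] for c in MANDATORY_COLUMNS}
            for c in OPTIONAL_COLUMNS:
                if c in df.columns and pd.notna(row[c]):
                    kwargs[c] = row[c]
            if "pos" in kwargs:
                kwargs["pos"] = int(kwargs["pos"])
            if "chrom" in kwargs:
                kwargs["chrom"] = str(kwargs["chrom"])
            try:
                records.append(
                    SnpAssociation(trait_id=trait_id, trait_type=trait_type, **kwargs)
                )
            except ValidationError as err:
                problems.append(f"row {idx}: {err}")
        if problems:
            raise ValidationError(
                f"{len(problems)} invalid row(s) in {trait_id!r}: " + " | ".join(problems)
            )
        return cls(trait_id=trait_id, records=records, provenance=provenance)


@dataclass
class MrReportRow:
    """One row of the per-method MR report (the ``mr`` layout)."""

    disease: str
    outcome_id: str
    exposure_id: str
    method: str
    nsnp: int
    or_: float
    or_lci95: float
    or_uci95: float
    pval: float
    fdr_p: float | None = None

    def __post_init__(self) -> None:
        vals = (self.or_lci95, self.or_, self.or_uci95)
        if all(v is not None and np.isfinite(v) for v in vals):
            if not (self.or_lci95 <= self.or_ <= self.or_uci95):
                raise ValidationError(
                    f"{self.exposure_id}->{self.outcome_id} [{self.method}]: "
                    f"CI ({self.or_lci95}, {self.or_uci95}) does not bracket OR {self.or_}"
                )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "case_control",
) -> SumStatsTable:
    """Read a tab-separated summary-statistics file into a validated table.

    Parameters
    ----------
    path
        TSV file with a header row.  Canonical column names are
        ``rsid, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval,
        n, n_case``; only the six mandatory ones need be present.
    column_map
        Optional ``canonical -> actual`` name mapping, e.g.
        ``{"rsid": "SNP", "effect_allele": "A1"}`` for PLINK-style headers.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        rename = {actual: canon for canon, actual in column_map.items()}
        missing_src = [a for a in rename if a not in df.columns]
        if missing_src:
            raise ConfigurationError(
                f"column_map names columns absent from {path.name}: {missing_src}"
            )
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"present: {list(df.columns)}; use column_map to rename"
        )
    table = SumStatsTable.from_frame(
        df,
        trait_id=trait_id if trait_id is not None else path.stem,
        trait_type=trait_type,
        provenance=str(path),
    )
    logger.info("read %d records from %s", len(table), path)
    return table


def write_sumstats(table: SumStatsTable, path: str | Path) -> Path:
    """Write a table in the canonical TSV format (inverse of read_sumstats)."""
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


# ---------------------------------------------------------------------------
# Report writing: fixed headers per layout, 3-decimal ORs, 3-significant-digit
# p-values, so written tables mirror the published ones and round-trip.
# ---------------------------------------------------------------------------

_MR_HEADER = [
    "disease", "outcome_id", "exposure_id", "method", "nsnp",
    "or", "or_lci95", "or_uci95", "pval", "fdr_p",
]
_META_HEADER = [
    "disease", "exposure_id", "k_studies",
    "fixed_or", "fixed_lci95", "fixed_uci95", "fixed_p",
    "random_or", "random_lci95", "random_uci95", "random_p",
    "q_stat", "q_pval", "tau2", "i2", "sensitivity_p",
]
COLOC_HEADER = [
    "SNP", "V.df1", "z.df1", "r.df1", "lABF.df1",
    "V.df2", "z.df2", "r.df2", "lABF.df2", "internal.sum.lABF", "SNP.PP.H4",
]


def _fmt_or(x: float | None) -> str:
    if x is None or not np.isfinite(x):
        return "NA"
    return f"{x:.3f}"


def _fmt_p(x: float | None) -> str:
    if x is None or not np.isfinite(x):
        return "NA"
    return f"{x:.3g}"


def write_report(
    rows: Sequence | object,
    path: str | Path,
    layout: str,
    annotations: Mapping[str, str] | None = None,
) -> Path:
    """Write MR / meta / coloc results as a fixed-layout TSV report.

    ``layout`` is one of ``mr`` (collection of :class:`MrReportRow`), ``meta``
    (collection of ``MetaResult``), or ``coloc`` (one or more ``ColocResult``;
    the regional posteriors PP.H0..PP.H4 are appended as ``#`` comment lines so
    the per-SNP block reads back cleanly).  ``annotations`` adds constant
    trailing columns (the pipeline uses this for the config hash and seed).
    """
    path = Path(path)
    if layout not in ("mr", "meta", "coloc"):
        raise ConfigurationError(f"unknown report layout {layout!r}")
    if rows is None or (hasattr(rows, "__len__") and len(rows) == 0):
        raise ValidationError("write_report: empty rows")
    ann_cols = list(annotations) if annotations else []
    ann_vals = [str(annotations[c]) for c in ann_cols] if annotations else []

    lines: list[str] = []
    footer: list[str] = []
    if layout == "mr":
        lines.append("\t".join(_MR_HEADER + ann_cols))
        for r in rows:
            lines.append("\t".join(
                [r.disease, r.outcome_id, r.exposure_id, r.method, str(int(r.nsnp)),
                 _fmt_or(r.or_), _fmt_or(r.or_lci95), _fmt_or(r.or_uci95),
                 _fmt_p(r.pval), _fmt_p(r.fdr_p)] + ann_vals
            ))
    elif layout == "meta":
        lines.append("\t".join(_META_HEADER + ann_cols))
        for r in rows:
            lines.append("\t".join(
                [r.group, r.exposure_id, str(int(r.k_studies)),
                 _fmt_or(r.fixed_or), _fmt_or(r.fixed_lci), _fmt_or(r.fixed_uci),
                 _fmt_p(r.fixed_p),
                 _fmt_or(r.random_or), _fmt_or(r.random_lci), _fmt_or(r.random_uci),
                 _fmt_p(r.random_p),
                 f"{r.q_stat:.4g}", _fmt_p(r.q_pval), f"{r.tau2:.4g}", f"{r.i2:.3f}",
                 _fmt_p(r.sensitivity_p)] + ann_vals
            ))
    else:  # coloc
        results = rows if isinstance(rows, (list, tuple)) else [rows]
        has_id = len(results) > 1
        header = (["Co-localization-ID"] if has_id else []) + COLOC_HEADER
        lines.append("\t".join(header + ann_cols))
        for res in results:
            tab = res.snp_table
            for _, row in tab.iterrows():
                cells = ([getattr(res, "coloc_id", "")] if has_id else []) + [
                    str(row["SNP"])
                ] + [f"{row[c]:.10g}" for c in COLOC_HEADER[1:]]
                lines.append("\t".join(cells + ann_vals))
            pp = res.pp
            footer.append(
                "# " + (f"{res.coloc_id}: " if getattr(res, "coloc_id", "") else "")
                + "\t".join(f"PP.{h}={pp[h]:.6g}" for h in ("H0", "H1", "H2", "H3", "H4"))
            )

    path.write_text("\n".join(lines + footer) + "\n")
    logger.info("wrote %s report with %d rows to %s", layout, len(lines) - 1, path)
    return path


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read an rsid exclusion list: one rsid per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            out.add(token)
    return out


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square r-squared matrix as TSV with an rsid header row/column."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise ValidationError("LD matrix rows and columns name different rsids")
    return ld
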
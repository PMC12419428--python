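"""End-to-end orchestration: MR fits, meta-analysis, colocalization, ROC.

The three-step design: Step 1 runs instrument selection, harmonization, the
estimator battery, and the sensitivity battery for every exposure/outcome
pair; Step 2 pools the per-outcome IVW estimates within disease groups;
Step 3 sends meta-analytically positive (FDR-gated) pairs to regional
colocalization, optionally followed by ROC evaluation of candidate genes on
a provided expression matrix.  All tunables live in one YAML config; every
report row carries the config hash and seed, and a MANIFEST records each
produced file with a content hash and the completion state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments, meta_analysis, mr_estimators, sensitivity
from .coloc_abf import coloc_posteriors, extract_region, trait_from_sumstats
from .roc_diag import auc_with_ci
from .sumstats_io import (
    ConfigurationError,
    MrReportRow,
    PipelineError,
    read_exclusion_list,
    read_ld_matrix,
    read_sumstats,
    write_report,
)

logger = logging.getLogger("mrdietcvd")

DEFAULT_THRESHOLDS: dict[str, float] = {
    "p_instrument": 5e-6,
    "ld_r2": 0.001,
    "ld_window_kb": 10_000,
    "alpha": 0.05,
    "fdr_alpha": 0.1,
    "pp_h4": 0.7,
    "auc_flag": 0.6,
    "palindromic_eaf_limit": 0.42,
}
DEFAULT_PRIORS: dict[str, float] = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}
_THRESHOLD_RANGES = {
    "p_instrument": (0.0, 1.0), "ld_r2": (0.0, 1.0), "alpha": (0.0, 1.0),
    "fdr_alpha": (0.0, 1.0), "pp_h4": (0.0, 1.0), "auc_flag": (0.0, 1.0),
    "palindromic_eaf_limit": (0.0, 0.5),
}


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults mirror the analysis protocol."""

    exposures: list[dict]
    outcomes: list[dict]
    out_dir: str
    seed: int
    exclusion_list: str | None = None
    ld_matrix: str | None = None
    expression_matrix: str | None = None
    expression_labels: str | None = None
    roc_genes: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ConfigurationError("config lists zero exposures")
        if not self.outcomes:
            raise ConfigurationError("config lists zero outcomes")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            if not (lo < merged[key] < hi) and merged[key] != lo:
                if not (lo <= merged[key] <= hi):
                    raise ConfigurationError(
                        f"threshold {key}={merged[key]} outside [{lo}, {hi}]"
                    )
        self.thresholds = merged
        pri = dict(DEFAULT_PRIORS)
        pri.update(self.priors)
        self.priors = pri
        for spec_ in self.outcomes:
            if "disease" not in spec_:
                raise ConfigurationError(
                    f"outcome {spec_.get('id', '?')!r} lacks a disease group label"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded,
        so identical analyses written to different directories match)."""
        payload = asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, state: str, files: list[Path], cfg: PipelineConfig):
    manifest = {
        "state": state,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "files": {p.name: _sha256(p) for p in files if p.exists()},
    }
    (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute Steps 1–3 and write the report files into ``cfg.out_dir``.

    Returns a mapping of artifact name to path (``table1``, ``table2``,
    ``sensitivity``, and when produced ``table3`` and ``roc``, plus ``log``
    and ``manifest``).  On a stage failure the partial outputs are kept, the
    MANIFEST marks the state, and a :class:`PipelineError` names the stage
    and the offending pair.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    produced: list[Path] = []
    ann = {"config_hash": cfg.config_hash, "seed": str(cfg.seed)}
    thr = cfg.thresholds

    def fail(stage: str, pair: str, err: Exception) -> PipelineError:
        _write_manifest(out_dir, f"failed at {stage} ({pair})", produced, cfg)
        logger.removeHandler(handler)
        handler.close()
        return PipelineError(f"stage {stage!r} failed for {pair}: {err}")

    try:
        exclusion = (
            read_exclusion_list(cfg.exclusion_list) if cfg.exclusion_list else frozenset()
        )
        ld = read_ld_matrix(cfg.ld_matrix) if cfg.ld_matrix else None
        exposures = {
            e["id"]: read_sumstats(e["path"], e.get("column_map"), trait_id=e["id"])
            for e in cfg.exposures
        }
        outcomes = {
            o["id"]: read_sumstats(o["path"], o.get("column_map"), trait_id=o["id"])
            for o in cfg.outcomes
        }
    except Exception as err:  # noqa: BLE001 - any load failure aborts cleanly
        raise fail("load", "inputs", err) from err
    grouping: dict[str, list[str]] = {}
    for o in cfg.outcomes:
        grouping.setdefault(o["disease"], []).append(o["id"])
    disease_of = {o["id"]: o["disease"] for o in cfg.outcomes}

    # ---- Step 1: per-pair MR + sensitivity --------------------------------
    table1: list[MrReportRow] = []
    sens_rows: list[dict] = []
    harmonized: dict[tuple[str, str], instruments.HarmonizedSet] = {}
    for exp_id, exp_table in exposures.items():
        for out_id, out_table in outcomes.items():
            pair = f"{exp_id} -> {out_id}"
            try:
                iv = instruments.select_instruments(
                    exp_table, thr["p_instrument"], exclusion
                )
                iv = instruments.ld_clump(
                    iv, ld.loc[iv.rsids(), iv.rsids()] if ld is not None else None,
                    thr["ld_r2"], thr["ld_window_kb"],
                )
                h = instruments.harmonize(
                    iv, out_table, thr["palindromic_eaf_limit"]
                )
                harmonized[(exp_id, out_id)] = h
                ests = mr_estimators.run_all(h, alpha=thr["alpha"], seed=cfg.seed)
                for est in ests:
                    table1.append(MrReportRow(
                        disease=disease_of[out_id], outcome_id=out_id,
                        exposure_id=exp_id, method=est.method, nsnp=est.nsnp,
                        or_=est.or_, or_lci95=est.or_lci95, or_uci95=est.or_uci95,
                        pval=est.pval,
                    ))
                rep = sensitivity.sensitivity_report(h, alpha=thr["alpha"])
                sens_rows.append({
                    "exposure_id": exp_id, "outcome_id": out_id, "nsnp": h.nsnp,
                    "q_stat": rep.q_stat, "q_pval": rep.q_pval, "i2": rep.i2,
                    "egger_intercept": rep.egger_intercept,
                    "egger_intercept_se": rep.egger_intercept_se,
                    "egger_intercept_p": rep.egger_intercept_p,
                    "steiger_direction": rep.steiger_direction,
                    "steiger_pval": rep.steiger_pval,
                    "influential": ";".join(rep.influential),
                })
            except Exception as err:  # noqa: BLE001
                raise fail("mr", pair, err) from err

    fdr = sensitivity.bh_adjust(
        [r.pval for r in table1], grouping=[r.outcome_id for r in table1]
    )
    for row, adj in zip(table1, fdr):
        row.fdr_p = float(adj)
    t1_path = write_report(table1, out_dir / "table1.tsv", "mr", annotations=ann)
    produced.append(t1_path)
    sens_path = out_dir / "sensitivity.tsv"
    pd.DataFrame(sens_rows).assign(**ann).to_csv(sens_path, sep="\t", index=False)
    produced.append(sens_path)

    # ---- Step 2: meta-analysis per disease group --------------------------
    try:
        table2 = meta_analysis.meta_group(table1, grouping)
    except Exception as err:  # noqa: BLE001
        raise fail("meta", "all groups", err) from err
    t2_path = write_report(table2, out_dir / "table2.tsv", "meta", annotations=ann)
    produced.append(t2_path)

    # ---- Step 3: coloc on meta-positive pairs, then optional ROC ----------
    meta_fdr = sensitivity.bh_adjust([m.fixed_p for m in table2])
    positives = [
        m for m, adj in zip(table2, meta_fdr) if adj < thr["fdr_alpha"]
    ]
    logger.info(
        "step 3 gate: %d of %d meta results pass FDR < %g",
        len(positives), len(table2), thr["fdr_alpha"],
    )
    coloc_results = []
    for m in positives:
        for out_id in grouping[m.group]:
            pair = f"{out_id};{m.exposure_id}"
            if (m.exposure_id, out_id) not in harmonized:
                continue
            try:
                out_table = outcomes[out_id]
                exp_table = exposures[m.exposure_id]
                shared = set(exp_table.rsids()) & set(out_table.rsids())
                with_pos = [
                    r for r in out_table if r.rsid in shared and r.pos is not None
                ]
                if not with_pos:
                    logger.warning("coloc skipped for %s: no positioned SNPs", pair)
                    continue
                top = min(with_pos, key=lambda r: r.pval)
                reg_out = extract_region(out_table, top.chrom, top.pos)
                reg_exp = extract_region(exp_table, top.chrom, top.pos)
                keep = sorted(
                    set(reg_out.rsids()) & set(reg_exp.rsids()),
                    key=reg_out.rsids().index,
                )
                reg_out.records = [r for r in reg_out.records if r.rsid in keep]
                reg_exp_by = {r.rsid: r for r in reg_exp.records}
                reg_exp.records = [reg_exp_by[r.rsid] for r in reg_out.records]
                res = coloc_posteriors(
                    trait_from_sumstats(reg_out), trait_from_sumstats(reg_exp),
                    priors=cfg.priors,
                )
                res.coloc_id = pair
                res.pp_h4_positive = res.pp["H4"] > thr["pp_h4"]
                coloc_results.append(res)
            except Exception as err:  # noqa: BLE001
                raise fail("coloc", pair, err) from err
    paths = {"table1": t1_path, "table2": t2_path, "sensitivity": sens_path}
    if coloc_results:
        t3_path = write_report(
            coloc_results, out_dir / "table3.tsv", "coloc", annotations=ann
        )
        produced.append(t3_path)
        paths["table3"] = t3_path

    if cfg.expression_matrix and cfg.expression_labels:
        try:
            expr = pd.read_csv(cfg.expression_matrix, sep="\t", index_col=0)
            lab = pd.read_csv(cfg.expression_labels, sep="\t", index_col=0)
            labels = lab.iloc[:, 0].reindex(expr.columns).to_numpy(int)
            genes = cfg.roc_genes or list(expr.index)
            roc_rows = []
            for g in genes:
                res = auc_with_ci(expr.loc[g].to_numpy(), labels, seed=cfg.seed)
                roc_rows.append({
                    "gene": g, "auc": res.auc, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "method": res.method,
                    "high_accuracy": res.auc > thr["auc_flag"],
                })
            roc_path = out_dir / "roc.tsv"
            pd.DataFrame(roc_rows).assign(**ann).to_csv(roc_path, sep="\t", index=False)
            produced.append(roc_path)
            paths["roc"] = roc_path
        except Exception as err:  # noqa: BLE001
            raise fail("roc", "expression matrix", err) from err

    _write_manifest(out_dir, "complete", produced, cfg)
    paths["log"] = log_path
    paths["manifest"] = out_dir / "MANIFEST.json"
    logger.removeHandler(handler)
    handler.close()
    return paths
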
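"""Instrument selection, clumping, and harmonization semantics."""

import numpy as np
import pandas as pd
import pytest

from mrdietcvd import ValidationError, harmonize, ld_clump, select_instruments
from mrdietcvd.instruments import EmptyInstrumentsError
from mrdietcvd.sumstats_io import SumStatsTable

from conftest import make_table


def test_p_threshold_filter():
    table = make_table([
        {"rsid": "rs1", "pval": 1e-7},
        {"rsid": "rs2", "pval": 1e-5, "pos": 2000},
        {"rsid": "rs3", "pval": 1e-4, "pos": 3000},
    ])
    kept = select_instruments(table, p_threshold=5e-6)
    assert kept.rsids() == ["rs1"]


def test_exclusion_list_removes_confounder_snps():
    table = make_table([
        {"rsid": "rs1", "pval": 1e-7},
        {"rsid": "rs2", "pval": 1e-8, "pos": 2000},
    ])
    kept = select_instruments(table, exclusion_list={"rs2"})
    assert kept.rsids() == ["rs1"]


def test_combined_filter_arithmetic():
    specs = [
        {"rsid": f"rs{i}", "pval": p, "pos": 1000 * (i + 1)}
        for i, p in enumerate(
            [1e-8, 1e-7, 1e-7, 1e-6, 1e-3, 1e-2, 0.1, 0.2, 0.5, 0.9]
        )
    ]
    table = make_table(specs)
    kept = select_instruments(table, p_threshold=5e-6, exclusion_list={"rs1"})
    assert len(kept) == 3  # 4 below threshold, 1 of those excluded


def test_empty_survivors_error_names_both_filters():
    table = make_table([{"rsid": "rs1", "pval": 0.5}])
    with pytest.raises(EmptyInstrumentsError, match="confounder"):
        select_instruments(table, p_threshold=5e-6)


def _clump_fixture():
    table = make_table([
        {"rsid": "rs1", "pval": 1e-8, "pos": 1000},
        {"rsid": "rs2", "pval": 1e-7, "pos": 2000},
        {"rsid": "rs3", "pval": 1e-6, "pos": 3000},
    ])
    ld = pd.DataFrame(
        [[1.0, 0.5, 0.0005], [0.5, 1.0, 0.0002], [0.0005, 0.0002, 1.0]],
        index=["rs1", "rs2", "rs3"], columns=["rs1", "rs2", "rs3"],
    )
    return table, ld


def test_greedy_clump_trace():
    table, ld = _clump_fixture()
    kept = ld_clump(table, ld)
    assert kept.rsids() == ["rs1", "rs3"]


def test_clump_single_candidate_kept():
    table = make_table([{"rsid": "rs1", "pval": 1e-8}])
    assert ld_clump(table, None).rsids() == ["rs1"]


def test_clump_outside_window_ignores_ld():
    table = make_table([
        {"rsid": "rs1", "pval": 1e-8, "pos": 1000},
        {"rsid": "rs2", "pval": 1e-7, "pos": 1000 + 20_000_000},
    ])
    ld = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]],
                      index=["rs1", "rs2"], columns=["rs1", "rs2"])
    assert len(ld_clump(table, ld, window_kb=10_000)) == 2


def test_clump_order_independent():
    table, ld = _clump_fixture()
    shuffled = SumStatsTable(
        trait_id=table.trait_id, records=[table.records[i] for i in (2, 0, 1)]
    )
    a = set(ld_clump(table, ld).rsids())
    b = set(ld_clump(shuffled, ld.loc[shuffled.rsids(), shuffled.rsids()]).rsids())
    assert a == b == {"rs1", "rs3"}


def test_clump_dimension_mismatch():
    table, _ = _clump_fixture()
    with pytest.raises(ValidationError, match="shape"):
        ld_clump(table, np.eye(2))


def test_harmonize_identity():
    exp = make_table([{"rsid": "rs1", "beta": 0.1, "eaf": 0.3}], trait_id="e")
    out = make_table([{"rsid": "rs1", "beta": -0.05, "eaf": 0.31}], trait_id="o")
    h = harmonize(exp, out)
    assert h.pairs.loc[0, "beta_y"] == pytest.approx(-0.05)
    assert h.pairs.loc[0, "eaf_y"] == pytest.approx(0.31)


def test_harmonize_swapped_alleles_flip_beta_and_eaf():
    exp = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G",
                       "beta": 0.1, "eaf": 0.3}], trait_id="e")
    out = make_table([{"rsid": "rs1", "effect_allele": "G", "other_allele": "A",
                       "beta": -0.05, "eaf": 0.7}], trait_id="o")
    h = harmonize(exp, out)
    assert h.pairs.loc[0, "beta_y"] == pytest.approx(0.05)
    assert h.pairs.loc[0, "eaf_y"] == pytest.approx(0.3)


def test_harmonize_strand_complement_aligned():
    exp = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G",
                       "beta": 0.1}], trait_id="e")
    out = make_table([{"rsid": "rs1", "effect_allele": "T", "other_allele": "C",
                       "beta": 0.02}], trait_id="o")
    h = harmonize(exp, out)
    assert h.pairs.loc[0, "beta_y"] == pytest.approx(0.02)


def test_palindromic_ambiguous_removed():
    exp = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
                       "eaf": 0.49},
                      {"rsid": "rs2", "pos": 2000}], trait_id="e")
    out = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
                       "eaf": 0.48},
                      {"rsid": "rs2", "pos": 2000}], trait_id="o")
    h = harmonize(exp, out)
    assert ("rs1", "palindromic") in h.removed
    assert h.pairs["rsid"].tolist() == ["rs2"]


def test_palindromic_clear_frequency_kept():
    exp = make_table([{"rsid": "rs1", "effect_allele": "C", "other_allele": "G",
                       "eaf": 0.1}], trait_id="e")
    out = make_table([{"rsid": "rs1", "effect_allele": "C", "other_allele": "G",
                       "eaf": 0.12, "beta": 0.2}], trait_id="o")
    h = harmonize(exp, out)
    assert h.pairs["rsid"].tolist() == ["rs1"]
    assert h.pairs.loc[0, "beta_y"] == pytest.approx(0.2)


def test_allele_mismatch_removed_with_reason():
    exp = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G"},
                      {"rsid": "rs2", "pos": 2000}], trait_id="e")
    out = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "C"},
                      {"rsid": "rs2", "pos": 2000}], trait_id="o")
    h = harmonize(exp, out)
    assert ("rs1", "allele_mismatch") in h.removed


def test_no_shared_rsids_distinct_error():
    exp = make_table([{"rsid": "rs1"}], trait_id="e")
    out = make_table([{"rsid": "rs2"}], trait_id="o")
    with pytest.raises(EmptyInstrumentsError, match="no shared"):
        harmonize(exp, out)


def test_kept_and_removed_partition_joined_rsids():
    exp = make_table([
        {"rsid": "rs1"},
        {"rsid": "rs2", "pos": 2000, "effect_allele": "A", "other_allele": "T",
         "eaf": 0.5},
        {"rsid": "rs3", "pos": 3000},
    ], trait_id="e")
    out = make_table([
        {"rsid": "rs1"},
        {"rsid": "rs2", "pos": 2000, "effect_allele": "A", "other_allele": "T",
         "eaf": 0.5},
        {"rsid": "rs3", "pos": 3000},
    ], trait_id="o")
    h = harmonize(exp, out)
    kept = set(h.pairs["rsid"])
    removed = {r for r, _ in h.removed}
    assert kept | removed == {"rs1", "rs2", "rs3"}
    assert kept & removed == set()


def test_harmonize_idempotent():
    exp = make_table([
        {"rsid": "rs1", "beta": 0.1, "eaf": 0.3},
        {"rsid": "rs2", "pos": 2000, "effect_allele": "C", "other_allele": "T",
         "beta": -0.2, "eaf": 0.2},
    ], trait_id="e")
    out = make_table([
        {"rsid": "rs1", "effect_allele": "G", "other_allele": "A",
         "beta": 0.05, "eaf": 0.7},
        {"rsid": "rs2", "pos": 2000, "effect_allele": "T", "other_allele": "C",
         "beta": 0.3, "eaf": 0.8},
    ], trait_id="o")
    h1 = harmonize(exp, out)
    # Rebuild tables from the harmonized pairs and harmonize again.
    out2 = make_table([
        {"rsid": r["rsid"], "pos": 1000 * (i + 1),
         "effect_allele": r["effect_allele"], "other_allele": r["other_allele"],
         "beta": r["beta_y"], "eaf": r["eaf_y"], "se": r["se_y"]}
        for i, (_, r) in enumerate(h1.pairs.iterrows())
    ], trait_id="o")
    h2 = harmonize(exp, out2)
    assert np.allclose(h1.pairs["beta_y"], h2.pairs["beta_y"])
    assert np.allclose(h1.pairs["eaf_y"], h2.pairs["eaf_y"])
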
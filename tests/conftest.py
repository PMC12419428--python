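import numpy as np
import pandas as pd
import pytest

from mrdietcvd import HarmonizedSet, SnpAssociation, SumStatsTable
from mrdietcvd.instruments import PAIR_COLUMNS


def make_snp(rsid="rs1", **kw):
    defaults = dict(
        rsid=rsid, chrom="1", pos=1000, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.1, se=0.02, pval=1e-8, n=100_000, n_case=50_000,
    )
    defaults.update(kw)
    return SnpAssociation(**defaults)


def make_table(specs, trait_id="trait"):
    """Build a SumStatsTable from a list of kwargs dicts."""
    return SumStatsTable(
        trait_id=trait_id,
        records=[make_snp(**s) for s in specs],
    )


def make_harmonized(beta_x, se_x, beta_y, se_y, n_x=100_000, n_y=100_000):
    """HarmonizedSet straight from effect arrays (already aligned)."""
    k = len(beta_x)
    pairs = pd.DataFrame({
        "rsid": [f"rs{j + 1}" for j in range(k)],
        "effect_allele": ["A"] * k,
        "other_allele": ["G"] * k,
        "beta_x": np.asarray(beta_x, float),
        "se_x": np.asarray(se_x, float),
        "beta_y": np.asarray(beta_y, float),
        "se_y": np.asarray(se_y, float),
        "eaf_x": [0.3] * k,
        "eaf_y": [0.3] * k,
        "pval_x": [1e-8] * k,
        "n_x": [float(n_x)] * k,
        "n_y": [float(n_y)] * k,
    }, columns=PAIR_COLUMNS)
    return HarmonizedSet("exp", "out", pairs)


@pytest.fixture
def harmonized_from_ratios():
    """Harmonized set whose Wald ratios and ratio SEs are exactly as given
    (beta_x = 1 everywhere, so ratio = beta_y and ratio_se = se_y)."""

    def _build(ratios, ratio_ses):
        k = len(ratios)
        return make_harmonized(
            beta_x=np.ones(k), se_x=np.full(k, 1e-6),
            beta_y=ratios, se_y=ratio_ses,
        )

    return _build
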
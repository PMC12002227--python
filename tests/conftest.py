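import numpy as np
import pandas as pd
import pytest

from chdburden.records import VARIANT_COLUMNS, FilterThresholds
from chdburden.simulate import CohortConfig, sample_mutabilities, simulate_cohort


def make_variant(**overrides) -> dict:
    """A valid variant-table row with sensible defaults, as a dict."""
    row = {
        "chrom": "chr1",
        "pos": 1_000_100,
        "ref": "A",
        "alt": "T",
        "gene": "G0001",
        "consequence": "missense",
        "metasvm": "D",
        "maf_bravo": 0.0,
        "maf_esp": 0.0,
        "maf_gnomad": 0.0,
        "cohort_ac": 1,
        "cohort_an": 23110,
        "origin": "de_novo",
        "sample_id": "F00001-P",
        "family_id": "F00001",
        "protein_pos": 50,
        "aa_ref": "G",
        "aa_alt": "C",
    }
    row.update(overrides)
    return row


def variant_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@pytest.fixture(scope="session")
def small_mutability():
    return sample_mutabilities(30, seed=11)


@pytest.fixture(scope="session")
def medium_cohort():
    """A moderate cohort with planted risk genes, shared across tests.

    Scaled down from the study for test runtime; the within-cohort MAF
    threshold is scaled accordingly (1 allele / 2 x 1500 probands).
    """
    mut = sample_mutabilities(60, seed=5)
    cfg = CohortConfig(
        n_trios=2000,
        n_singletons=1500,
        n_controls=30000,
        n_genes=60,
        risk_gene_fraction=10 / 60,
        dnm_enrichment=15.0,
        transmission_prob=0.8,
        carrier_freq=3e-3,
        seed=17,
    )
    cohort = simulate_cohort(cfg, mut)
    return cohort


@pytest.fixture(scope="session")
def loose_thresholds():
    """Rarity thresholds matching the small test cohorts' chromosome counts."""
    return FilterThresholds(max_pop_maf=1e-5, max_cohort_maf=5e-3)
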
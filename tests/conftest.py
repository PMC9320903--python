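import numpy as np
import pandas as pd
import pytest

from trioscan.core import Callset, SiteCall, Thresholds, Trio, TrioCohort
from trioscan.panels import ExpressionTable
from trioscan.synthetic import SimConfig, simulate_cohort, write_fixture_bundle


def make_site(
    chrom="1",
    pos=100,
    ref="A",
    alt="T",
    qual=500.0,
    gts=(1, 0, 0),
    gq=None,
    ad=None,
):
    """Build a SiteCall; GQ defaults to 99 for called genotypes."""
    n = len(gts)
    gts = np.array(gts, dtype=np.int8)
    if gq is None:
        gq = np.where(gts == -1, np.nan, 99.0)
    if ad is None:
        ad_ref = np.full(n, 30)
        ad_alt = np.where(gts == 1, 15, np.where(gts == 2, 30, 0))
    else:
        ad_ref, ad_alt = ad
    return SiteCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        genotypes=gts,
        gq=np.asarray(gq, dtype=float),
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )


def make_callset(samples, sites):
    return Callset(samples, sites)


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def trio_cohort():
    """One trio (P1, FA1, MO1) plus two extra case probands and a control."""
    trios = [
        Trio("P1", "FA1", "MO1"),
        Trio("P2", "FA2", "MO2"),
        Trio("P3", "FA3", "MO3"),
    ]
    return TrioCohort(
        trios=trios,
        cases={"P1", "P2", "P3"},
        controls={"C1"},
    )


@pytest.fixture
def trio_samples():
    return ["P1", "FA1", "MO1", "P2", "FA2", "MO2", "P3", "FA3", "MO3", "C1"]


@pytest.fixture
def expression_simple():
    df = pd.DataFrame(
        {
            "4wpc": [5.0, 0.0, 1.9, 0.0],
            "5wpc": [0.1, 0.0, 1.0, 0.0],
            "6wpc": [0.0, 2.0, 0.5, 0.0],
            "7wpc": [0.0, 0.0, 1.8, 0.0],
            "8wpc": [0.0, 0.0, 0.0, 0.0],
            "newborn": [0.0, 0.0, 50.0, 9.0],
            "adult": [1.0, 3.0, 60.0, 9.0],
        },
        index=pd.Index(["EXPA", "EXPB", "LOWC", "OFFD"], name="gene"),
    )
    return ExpressionTable(df)


@pytest.fixture(scope="session")
def sim_small():
    """Shared mid-size synthetic cohort exercising every injection type."""
    cfg = SimConfig(
        n_trios=15,
        n_controls=50,
        n_genes=15,
        variants_per_gene=3.0,
        denovo_rate=1.0,
        mosaic_rate=1.0,
        carrier_freq=0.10,
        n_common_variants=150,
        related_pairs=1,
        quality_noise=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_small_bundle(sim_small, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(sim_small, out / "fix")
    return out / "fix"
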
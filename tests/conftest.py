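import numpy as np
import pandas as pd
import pytest

import allelomethyl as am

EQUAL_MEANS = {"CG": 0.6, "CHH": 0.3, "CHG": 0.2}


@pytest.fixture(scope="session")
def default_dataset() -> am.SyntheticDataset:
    """One simulation under the default study conditions."""
    return am.simulate_dataset(am.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_dataset() -> am.SyntheticDataset:
    """Small dataset without planted DMRs or per-gene jitter.

    Gene propensity is pinned to the neutral value, so every region sits at
    the configured base level: body/upstream CG at 0.6 exactly.
    """
    cfg = am.SimulationConfig(
        seed=7, n_chroms=1, chrom_len=180_000, n_genes=20,
        context_means=EQUAL_MEANS, gene_jitter_sd=0.0,
        gene_propensity_range=(0.45, 0.45), dmr_spec=(), de_fraction=0.0,
    )
    return am.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def dmr_benchmark() -> am.SyntheticDataset:
    """Planted-DMR benchmark: equal tissue means so the planted intervals are
    the only true flower-vs-leaf differences (delta 0.3, 1 kb, 50 planted,
    coverage 30)."""
    cfg = am.SimulationConfig(seed=21, context_means=EQUAL_MEANS, gene_jitter_sd=0.0)
    return am.simulate_dataset(cfg)


def allele_pairs_for(ds: am.SyntheticDataset) -> pd.DataFrame:
    hap_a, hap_b = ds.config.haplotypes
    blocks, members = am.chain_anchors(ds.anchors, ds.genes[hap_a], ds.genes[hap_b])
    return am.call_allele_pairs(blocks, members)


def region_levels_by_tissue(ds: am.SyntheticDataset, hap: str) -> pd.DataFrame:
    frames = []
    for tissue in ds.config.tissues:
        lv = am.region_levels(ds.methylation[(hap, tissue)], ds.genes[hap])
        lv["tissue"] = tissue
        frames.append(lv)
    return pd.concat(frames, ignore_index=True)


def make_calls(rows) -> pd.DataFrame:
    """Call table from (chrom, pos, strand, context, coverage, methylated)."""
    return pd.DataFrame(rows, columns=am.io.METHYLATION_COLUMNS)


def make_genes(rows) -> pd.DataFrame:
    """Gene table from (gene_id, chrom, start, end, strand)."""
    return pd.DataFrame(rows, columns=am.io.GENE_COLUMNS)


def random_genome(rng: np.random.Generator, length: int, with_n=False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))
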
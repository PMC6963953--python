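import numpy as np
import pandas as pd
import pytest

from bulkmap import (
    BulkDesign,
    GenomeMap,
    ScanConfig,
    ThresholdConfig,
    TraitModel,
    assign_bulks,
    simulate_bulk_depths,
    simulate_f2_genotypes,
)

CHROM_LEN = 10_000_000
CAUSAL_POS = 5_000_000


def simulate_experiment_table(seed: int, causal: bool, mean_depth: float = 30.0,
                              n_individuals: int = 323, n_per_bulk: int = 50,
                              spacing: int = 50_000) -> pd.DataFrame:
    """One full synthetic bulked-segregant experiment -> VariantTable."""
    gmap = GenomeMap.uniform({"A01": CHROM_LEN}, spacing=spacing, seed=seed)
    trait = TraitModel("A01", CAUSAL_POS) if causal else None
    geno = simulate_f2_genotypes(gmap, trait, n_individuals, seed=seed)
    design = BulkDesign(n_per_bulk=n_per_bulk, mean_depth=mean_depth,
                        base_error=0.001, seed=seed)
    bulks = assign_bulks(geno, gmap, trait, design)
    return simulate_bulk_depths(geno, bulks, gmap, design)


@pytest.fixture(scope="session")
def scan_cfg():
    # markers every 50 kb: 200 kb windows keep >= 3 variants per window
    return ScanConfig(window_size=200_000, step=20_000)


@pytest.fixture(scope="session")
def thr_cfg():
    return ThresholdConfig(confidence=0.99, null_reps=1000, seed=0, n_per_bulk=50)


@pytest.fixture
def small_variant_table():
    rng = np.random.default_rng(42)
    n = 40
    pos = np.sort(rng.choice(np.arange(1, 1_000_000), size=n, replace=False))
    depth = rng.poisson(30, size=(n, 2)) + 1
    alt = rng.binomial(depth, 0.5)
    return pd.DataFrame(
        {
            "chrom": "A01",
            "pos": pos,
            "variant_type": np.where(np.arange(n) % 4 == 0, "indel", "SNP"),
            "parent1_gt": "1/1",
            "parent2_gt": "0/0",
            "bulkA_ref_depth": depth[:, 0] - alt[:, 0],
            "bulkA_alt_depth": alt[:, 0],
            "bulkB_ref_depth": depth[:, 1] - alt[:, 1],
            "bulkB_alt_depth": alt[:, 1],
        }
    )


@pytest.fixture
def gene_table():
    return pd.DataFrame(
        {
            "gene_id": ["Bra000001", "Bra000002", "Bra000003"],
            "chrom": ["A01", "A01", "A02"],
            "start": [100, 5000, 100],
            "end": [900, 6000, 900],
            "strand": ["+", "-", "+"],
        }
    )
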
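import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polyshift import (
    FrequencyPanel,
    SimConfig,
    TraitSnpSet,
    build_population_structure,
    harmonize,
    select_trait_snps,
    simulate_frequency_panel,
    simulate_gwas_trait,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_model():
    return build_population_structure(2, 2, between_var=0.02, within_var=0.01)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    """A 2,000-SNP, 4-population cohort with 40 trait SNPs (read-only)."""
    cfg = SimConfig(n_snps=2000, n_trait_snps=40, seed=11)
    panel, ann = simulate_frequency_panel(small_model, cfg)
    gwas = simulate_gwas_trait(panel, cfg)
    return {"config": cfg, "panel": panel, "ann": ann, "gwas": gwas}


@pytest.fixture(scope="session")
def small_trait_snps(small_cohort):
    harmonized, _ = harmonize(small_cohort["gwas"], small_cohort["panel"])
    return select_trait_snps(
        harmonized, 1e-6, small_cohort["ann"].ld_block_series(), trait="trait1"
    )


def make_panel(freqs: dict[str, list[float]], region_of: dict[str, str],
               alleles=("A", "G")) -> FrequencyPanel:
    """Hand-built panel: freqs maps population -> allele1 frequencies."""
    n = len(next(iter(freqs.values())))
    ids = pd.Index([f"s{i}" for i in range(n)], name="snp_id")
    snps = pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "pos": (np.arange(n) + 1) * 100,
            "allele1": [alleles[0]] * n,
            "allele2": [alleles[1]] * n,
        },
        index=ids,
    )
    fdf = pd.DataFrame(freqs, index=ids, dtype=float)
    return FrequencyPanel(snps, fdf, region_of).validate()


def make_trait_snps(snp_ids, beta_abs, increasing="A", trait="t",
                    threshold=1e-6) -> TraitSnpSet:
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "trait_increasing_allele": [increasing] * len(snp_ids),
            "beta_abs": beta_abs,
            "p": [1e-9] * len(snp_ids),
            "ld_block_id": [f"b{i}" for i in range(len(snp_ids))],
        }
    )
    return TraitSnpSet(table, trait=trait, threshold=threshold)
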
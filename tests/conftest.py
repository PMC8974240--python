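import numpy as np
import pandas as pd
import pytest

from panelqtl.gwas import AssocRecord
from panelqtl.simulate import (
    GenotypeMatrix,
    PanelConfig,
    PlantedQtl,
    TruthSet,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def two_pop_config() -> PanelConfig:
    return PanelConfig(
        subpop_sizes={"A": 40, "B": 40},
        chrom_lengths=[10_000_000] * 3,
        n_snps=300,
        fst=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_pop_genotypes(two_pop_config) -> GenotypeMatrix:
    return simulate_genotypes(two_pop_config)


@pytest.fixture()
def tiny_genotypes() -> GenotypeMatrix:
    """4 accessions x 3 SNPs with hand-set dosages."""
    dosages = np.array([
        [0.0, 2.0, 0.0],
        [2.0, 2.0, 0.0],
        [0.0, 0.0, 2.0],
        [2.0, 0.0, 2.0],
    ])
    snp_map = pd.DataFrame({
        "snp": ["s1", "s2", "s3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 200, 150],
        "ref": ["A", "C", "G"],
        "alt": ["G", "T", "A"],
    })
    return GenotypeMatrix(dosages, snp_map, ["a1", "a2", "a3", "a4"],
                          ["X", "X", "Y", "Y"])


def make_assoc(pos, mlp=6.0, eff=1.0, panel="All", trait="Si", n_alt=10,
               chrom="1", snp=None):
    n_common = 100
    return AssocRecord(
        snp=snp or f"S{chrom}_{pos}", chrom=chrom, pos=pos,
        minus_log10_p=mlp, effect_common=eff,
        common_allele="A", alt_allele="G",
        n_common=n_common, n_alt=n_alt,
        pct_alt=round(100 * n_alt / (n_common + n_alt), 2),
        trait=trait, panel=panel,
    )


@pytest.fixture()
def assoc_factory():
    return make_assoc


@pytest.fixture()
def simple_truth() -> TruthSet:
    return TruthSet(
        planted_qtl=[PlantedQtl("T1", "1", 100, 1.0)],
        dag_arcs=[("T1", "T2", 0.5)],
        intercepts={"T1": 10.0, "T2": 5.0},
        noise_sd={"T1": 0.5, "T2": 0.5},
        polygenic_sd={"T1": 1.0, "T2": 1.0},
    )
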
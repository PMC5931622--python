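import numpy as np
import pandas as pd
import pytest

from grschd.cohort_sim import SimConfig, simulate_study
from grschd.io_formats import VariantWeight, WeightSet


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    cfg = SimConfig(n=3000, seed=42)
    cohort, genotypes, ws, scores = simulate_study(cfg)
    return {
        "config": cfg, "cohort": cohort, "genotypes": genotypes,
        "weights": ws, "scores": scores,
    }


@pytest.fixture()
def toy_weights():
    """Three individually weighted variants plus the 4-member haplotype."""
    variants = [
        VariantWeight("rs1", "A", "G", 0.10, in_grs51=True),
        VariantWeight("rs2", "T", "C", 0.05, in_grs51=True),
        VariantWeight("rs3", "G", "A", 0.30, in_grs51=True),
        VariantWeight("rs10507391", "A", "G", 0.0, in_grs51=True,
                      haplotype_member=True),
        VariantWeight("rs93155050", "A", "C", 0.0, in_grs51=True,
                      haplotype_member=True),
        VariantWeight("rs17222842", "G", "A", 0.0, in_grs51=True,
                      haplotype_member=True),
        VariantWeight("rs17216473", "A", "C", 0.0, in_grs51=True,
                      haplotype_member=True),
    ]
    return WeightSet(variants=variants)


def make_genotypes(dosages: dict, samples=None):
    """GenotypeMatrix from {rsid: [dosages]} counted on the effect allele."""
    from grschd.io_formats import GenotypeMatrix

    df = pd.DataFrame(dosages, dtype=float)
    if samples is not None:
        df.index = samples
    return GenotypeMatrix(
        dosages=df,
        counted_allele=pd.Series("EFFECT", index=df.columns),
    )
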
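import numpy as np
import pandas as pd
import pytest

from onsetprs.containers import GenotypeMatrix, SurvivalCohort
from onsetprs.syndata import SimulationConfig, simulate_genotypes, simulate_onset


def make_genotypes(dosages, chrom=None, pos=None, ea=None, oa=None):
    """Build a GenotypeMatrix from a plain (n_samples, n_variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chr": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else [1000 * (j + 1) for j in range(m)],
        "ea": ea if ea is not None else ["A"] * m,
        "oa": oa if oa is not None else ["G"] * m,
    })
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


def make_cohort(entry, exit_age, event, fh=None, **covs):
    entry = np.asarray(entry, float)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(entry))],
        "entry_age": entry,
        "exit_age": np.asarray(exit_age, float),
        "event": np.asarray(event, int),
        "fh": fh if fh is not None else np.zeros(len(entry), int),
    })
    for k, v in covs.items():
        df[k] = v
    return SurvivalCohort(df, covariates=list(covs))


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated dataset shared across tests."""
    cfg = SimulationConfig(n_samples=2000, n_variants=60,
                           ld_block_sizes=[6] * 10,
                           missing_rate=0.01, seed=42)
    geno = simulate_genotypes(cfg)
    cohort = simulate_onset(geno, cfg)
    return cfg, geno, cohort
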
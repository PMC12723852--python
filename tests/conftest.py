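import numpy as np
import pandas as pd
import pytest

from gmspop import GenotypeMatrix, MISSING


def make_matrix(calls, populations=None, chrom=None, pos_bp=None,
                sample_ids=None, snp_ids=None):
    """Build a GenotypeMatrix from a samples x snps array with defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    populations = populations or ["POP"] * n
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    snp_ids = snp_ids or [f"rs{j}" for j in range(m)]
    chrom = chrom or ["1"] * m
    pos_bp = pos_bp if pos_bp is not None else (np.arange(m) + 1) * 10_000
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos_cm": np.asarray(pos_bp) / 1e6,
            "pos_bp": pos_bp,
            "allele1": "A",
            "allele2": "G",
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def freq_table(freqs: dict, n_obs=100):
    """Small FreqTable from {pop: [freq,...]}; NaN means no data.

    ``n_obs`` is a scalar applied to every cell or a {pop: value} mapping.
    """
    from gmspop import FreqTable

    pops = list(freqs)
    f = np.array([freqs[p] for p in pops], dtype=float)
    m = f.shape[1]
    n = np.full(f.shape, n_obs if isinstance(n_obs, int) else 0, dtype=np.int64)
    if isinstance(n_obs, dict):
        for p, v in n_obs.items():
            n[pops.index(p)] = v
    n[np.isnan(f)] = 0
    snps = pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(m)],
        "chrom": "1",
        "pos_cm": np.arange(m) * 0.01,
        "pos_bp": (np.arange(m) + 1) * 10_000,
        "allele1": "A",
        "allele2": "G",
    })
    return FreqTable(populations=pops, freq=f, n_obs=n, snps=snps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_two_pop(rng):
    """60 samples in two drifted populations, 500 SNPs, some missing calls."""
    from gmspop import PopTree, SimConfig, simulate

    tree = PopTree(
        parents={"root": None, "A": "root", "B": "root"},
        drift={"A": 0.05, "B": 0.05},
        leaf_sizes={"A": 30, "B": 30},
    )
    config = SimConfig(n_snps=500, missing_rate=0.02, seed=777)
    G, truth = simulate(config, tree)
    return G, truth
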
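import numpy as np
import pytest

import npdr


@pytest.fixture(scope="session")
def tiny_genotypes() -> npdr.GenotypeMatrix:
    dosage = np.array([[0, 1, 2],
                       [1, 1, 0],
                       [2, 0, 1],
                       [1, 2, 1]], dtype=np.int8)
    return npdr.GenotypeMatrix([f"S{i}" for i in range(4)], ["A", "B", "C"], dosage)


@pytest.fixture(scope="session")
def small_epistasis_dataset():
    """One interacting-pair replicate small enough for per-test reuse."""
    G, y, truth = npdr.simulate_design("interact-pair", seed=20, h2=0.4,
                                       n_cases=100, n_controls=100)
    return G, y, truth


@pytest.fixture(scope="session")
def benchmark_epistasis_dataset():
    """Full-size pure-epistasis replicate: h2=0.4, MAF 0.2, 800/800, p=20."""
    G, y, truth = npdr.simulate_design("interact-pair", seed=7, h2=0.4)
    return G, y, truth


def make_confounded_dataset(seed, m_per=250, p_bg=400, fst=0.03, fc_lo=0.3,
                            prev=(0.2, 0.8)):
    """Two-subpopulation confound: the CONF SNP diverges in frequency between
    subpopulations (mirrored, fc vs 1-fc, so within-group diff distributions
    match) and disease prevalence differs by subpopulation (also mirrored, so
    within-group miss rates match), but CONF has no effect within either
    group.  Background SNPs follow a Balding-Nichols model so principal
    components recover the structure."""
    rng = np.random.default_rng(seed)
    m = 2 * m_per
    sub = np.repeat([0, 1], m_per)
    a = 0.25 * (1 - fst) / fst
    b = 0.75 * (1 - fst) / fst
    f = np.clip(rng.beta(a, b, size=(2, p_bg)), 0.05, 0.95)
    dosage = rng.binomial(2, f[sub], size=(m, p_bg))
    fc = np.array([fc_lo, 1 - fc_lo])
    conf = rng.binomial(2, fc[sub])
    dosage = np.column_stack([conf, dosage]).astype(np.int8)
    snps = ["CONF"] + [f"N{i}" for i in range(p_bg)]
    yv = (rng.random(m) < np.array(prev)[sub]).astype(float)
    G = npdr.GenotypeMatrix([f"S{i}" for i in range(m)], snps, dosage)
    return G, npdr.PhenotypeVector(yv, "binary"), sub
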
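import numpy as np
import pytest

from hybridgp import (
    HybridPedigree,
    LineGenotypes,
    compute_allele_freqs,
    center_line_genotypes,
)
from hybridgp.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Complete 12x10 factorial, 200 markers, mixed genetic architecture."""
    cfg = SimConfig(
        n1=12, n2=10, nsnp=200, design="complete", seed=3,
        var_A1=20, var_A2=10, var_D=3, var_AA11=2, var_AA22=2, var_AA12=2,
        var_r1=2, var_r2=2, var_e=10, n_epistatic_pairs=50, mu=50.0,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_two_line():
    """Two lines, one marker, calls (1, 0): the worked example panel."""
    g = LineGenotypes("g1", ["L1", "L2"], ["m1"], np.array([[1.0], [0.0]]))
    f = compute_allele_freqs(g)
    z = center_line_genotypes(g, f)
    return g, f, z


@pytest.fixture
def factorial_2x2():
    """Complete 2x2 factorial at one marker with parental calls (1, 0) in
    both groups: W column (-0.5, 0.5, 0.5, -0.5)."""
    g1 = LineGenotypes("g1", ["D1", "D2"], ["m1"], np.array([[1.0], [0.0]]))
    g2 = LineGenotypes("g2", ["F1", "F2"], ["m1"], np.array([[1.0], [0.0]]))
    hybrids = ["H11", "H12", "H21", "H22"]
    ped = HybridPedigree(
        hybrids,
        {"H11": "D1", "H12": "D1", "H21": "D2", "H22": "D2"},
        {"H11": "F1", "H12": "F2", "H21": "F1", "H22": "F2"},
    )
    return g1, g2, ped
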
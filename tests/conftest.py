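"""Shared fixtures: small synthetic genotype panels and traits.

All fixtures are deterministic; panels are sized for speed, not realism —
the evaluation module owns the larger calibration/power studies.
"""

import numpy as np
import pytest

from pgsepi import generate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """2000 x 1000 dosage panel over 22 chromosomes with moderate block LD."""
    return generate_genotypes(2000, 1000, 22, seed=42)


@pytest.fixture(scope="session")
def tiny_panel():
    """300 x 60 panel over 3 chromosomes for toy regression oracles."""
    return generate_genotypes(300, 60, 3, seed=7)


@pytest.fixture(scope="session")
def ld_panel():
    """Single-chromosome panel with strong within-block LD (rho=0.95)."""
    return generate_genotypes(1500, 400, 1, mean_block_length=10, block_rho=0.95, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
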
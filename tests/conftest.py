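"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

from qgpanel import qc_filter, simulate_genotypes, simulate_trait
from qgpanel.synth import SimConfig, TraitConfig


@pytest.fixture(scope="session")
def panel():
    """A QC-passed 250-line x ~800-marker panel with mild structure."""
    cfg = SimConfig(
        n_lines=250, n_markers=800, n_chromosomes=5, n_subpops=2, fst=0.15, seed=42
    )
    geno, _ = qc_filter(simulate_genotypes(cfg))
    return geno


@pytest.fixture(scope="session")
def structured_panel():
    """Two strongly diverged subpopulations (fst=0.3, 2000 markers)."""
    cfg = SimConfig(
        n_lines=200, n_markers=2000, n_chromosomes=5, n_subpops=2, fst=0.3, seed=7
    )
    geno, _ = qc_filter(simulate_genotypes(cfg))
    return geno


@pytest.fixture(scope="session")
def sparse_trait(panel):
    """A 5-QTL equal-effect trait (h2=0.8, 4 environments) plus its truth."""
    tc = TraitConfig(
        n_qtl=5, effect_distribution="equal", h2_target=0.8, n_environments=4, seed=6
    )
    pheno, truth = simulate_trait(panel, tc)
    return pheno, truth


@pytest.fixture(scope="session")
def polygenic_trait(panel):
    """A 50-QTL gaussian-effect trait (h2=0.9, 6 environments)."""
    tc = TraitConfig(n_qtl=50, h2_target=0.9, n_environments=6, seed=13)
    pheno, truth = simulate_trait(panel, tc)
    return pheno, truth
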
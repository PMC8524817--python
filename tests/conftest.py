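"""Shared fixtures: canonical templates and small seeded cohorts."""

from __future__ import annotations

import pytest

from cptrna.cloverleaf import parse_structure
from cptrna.synthetic_data import SimConfig, generate_cohort, make_trna_template


@pytest.fixture(scope="session")
def phe_template():
    """Canonical Phe-GAA cloverleaf template gene."""
    return make_trna_template("Phe", "GAA", seed=7)


@pytest.fixture(scope="session")
def phe_structure(phe_template):
    return parse_structure(phe_template)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-species cohort under default study conditions, fixed seed."""
    cfg = SimConfig(n_species=6, seed=11)
    species_tree, genes, truth, gene_trees = generate_cohort(cfg)
    return cfg, species_tree, genes, truth, gene_trees
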
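"""Shared synthetic designs; session-scoped so expensive generation runs once."""

from __future__ import annotations

import pytest

from coexnet.correlation import all_pairs
from coexnet.io import collapse_conditions
from coexnet.synthetic import (
    ModuleSpec,
    SyntheticSpec,
    generate_catalog,
    generate_compendium,
    generate_ontology,
)


@pytest.fixture(scope="session")
def null_design():
    """Structureless compendium: 200 genes x 155 conditions, no modules."""
    spec = SyntheticSpec(n_genes=200, modules=(), seed=7)
    compendium, truth = generate_compendium(spec)
    collapse_conditions(compendium)
    return spec, compendium, truth


@pytest.fixture(scope="session")
def module_design():
    """Three planted 20-gene modules (mixed signs) on 400 genes."""
    spec = SyntheticSpec(
        n_genes=400,
        modules=(
            ModuleSpec(20, 1.5, 0.3, 0.0),
            ModuleSpec(20, 1.5, 0.3, 0.3),
            ModuleSpec(20, 1.5, 0.3, 0.5),
        ),
        noise_sd=0.5,
        ontology_terms=30,
        seed=3,
    )
    compendium, truth = generate_compendium(spec)
    collapse_conditions(compendium)
    catalog = generate_catalog(spec, truth)
    dag, annmap = generate_ontology(spec, truth)
    corr = all_pairs(compendium.condition_log2, report_threshold=0.5)
    return spec, compendium, truth, catalog, dag, annmap, corr


@pytest.fixture(scope="session")
def regulator_design():
    """20 one-core SM clusters plus 2 planted out-of-cluster regulators
    sharing a latent factor with every core."""
    spec = SyntheticSpec(
        n_genes=600,
        modules=(),
        n_sm_clusters=20,
        sm_cluster_size_range=(4, 6),
        n_planted_regulators=2,
        regulator_loading_mean=1.5,
        noise_sd=0.5,
        core_negative_fraction=0.25,
        seed=5,
    )
    compendium, truth = generate_compendium(spec)
    collapse_conditions(compendium)
    catalog = generate_catalog(spec, truth)
    corr = all_pairs(compendium.condition_log2, report_threshold=0.5)
    return spec, compendium, truth, catalog, corr


@pytest.fixture(scope="session")
def coherence_design():
    """SM clusters placed on planted modules so cluster coherence is known;
    60% of clusters carry an embedded TF."""
    spec = SyntheticSpec(
        n_genes=500,
        modules=tuple(ModuleSpec(8, 1.5, 0.2, 0.0) for _ in range(10)),
        n_sm_clusters=10,
        sm_cluster_size_range=(8, 8),
        sm_clusters_on_modules=True,
        tf_embedded_fraction=0.6,
        noise_sd=0.5,
        seed=9,
    )
    compendium, truth = generate_compendium(spec)
    collapse_conditions(compendium)
    catalog = generate_catalog(spec, truth)
    corr = all_pairs(compendium.condition_log2, report_threshold=0.5)
    return spec, compendium, truth, catalog, corr
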
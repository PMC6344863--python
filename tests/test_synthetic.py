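"""Generator guarantees: determinism, planted-correlation strength, null
tails, catalog/cluster construction, and ontology structure."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from coexnet.correlation import spearman_rho
from coexnet.io import collapse_conditions
from coexnet.synthetic import (
    ModuleSpec,
    SyntheticSpec,
    generate_catalog,
    generate_compendium,
    generate_ontology,
)


class TestCompendium:
    def test_fixed_seed_is_bit_identical(self):
        spec = SyntheticSpec(n_genes=50, modules=(ModuleSpec(10),), seed=42)
        c1, _ = generate_compendium(spec)
        c2, _ = generate_compendium(spec)
        pd.testing.assert_frame_equal(c1.intensities, c2.intensities)
        assert c1.array_to_condition == c2.array_to_condition

    def test_default_replicate_layout_gives_283_arrays(self):
        spec = SyntheticSpec(n_genes=10, seed=0)
        comp, _ = generate_compendium(spec)
        assert len(comp.array_ids) == 283
        assert comp.n_conditions == 155

    def test_structureless_design_stays_below_half(self, null_design):
        """With no planted modules, no pair reaches |rho| = 0.5."""
        _, compendium, _ = null_design
        mat = compendium.condition_log2.to_numpy()
        from scipy.stats import rankdata

        z = rankdata(mat, axis=1)
        z = z - z.mean(axis=1, keepdims=True)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        rho = z @ z.T
        np.fill_diagonal(rho, 0.0)
        assert np.abs(rho).max() < 0.5

    def test_planted_module_is_strongly_correlated(self):
        """One 20-gene module at loading 1.5, noise 0.5: median within-module
        |rho| at least 0.7."""
        spec = SyntheticSpec(
            n_genes=100, modules=(ModuleSpec(20, 1.5, 0.0, 0.0),),
            noise_sd=0.5, seed=2,
        )
        comp, truth = generate_compendium(spec)
        collapse_conditions(comp)
        members = truth.module_genes(0)
        assert len(members) == 20
        rhos = [
            abs(spearman_rho(comp.condition_log2.loc[a], comp.condition_log2.loc[b]))
            for a, b in itertools.combinations(members, 2)
        ]
        assert np.median(rhos) >= 0.7

    def test_negative_fraction_plants_anticorrelation(self):
        spec = SyntheticSpec(
            n_genes=60, modules=(ModuleSpec(20, 1.5, 0.1, 0.5),), seed=8,
        )
        comp, truth = generate_compendium(spec)
        collapse_conditions(comp)
        signs = truth.loading_signs
        members = truth.module_genes(0)
        pos = [g for g in members if signs[g] == "+"]
        neg = [g for g in members if signs[g] == "-"]
        assert pos and neg
        rho = spearman_rho(
            comp.condition_log2.loc[pos[0]], comp.condition_log2.loc[neg[0]]
        )
        assert rho < -0.5

    def test_oversized_modules_rejected(self):
        spec = SyntheticSpec(n_genes=10, modules=(ModuleSpec(20),))
        with pytest.raises(ValueError, match="module sizes"):
            generate_compendium(spec)

    def test_linear_scale_matrix_is_positive(self, null_design):
        _, compendium, _ = null_design
        assert (compendium.intensities.to_numpy() > 0).all()


class TestCatalog:
    def test_clusters_are_contiguous_with_one_core(self, regulator_design):
        _, _, truth, catalog, _ = regulator_design
        t = catalog.table
        for cid, members in catalog.clusters().items():
            rows = t.loc[members].sort_values("start")
            # members form an interval in coordinate order on one chromosome
            chrom = rows["chromosome"].unique()
            assert len(chrom) == 1
            on_chrom = t[t["chromosome"] == chrom[0]].sort_values("start")
            pos = [on_chrom.index.get_loc(g) for g in rows.index]
            assert pos == list(range(min(pos), max(pos) + 1))
            assert rows["is_sm_core"].sum() == 1

    def test_planted_regulators_are_tfs_outside_clusters(self, regulator_design):
        _, _, truth, catalog, _ = regulator_design
        for g in truth.planted_regulator_ids:
            assert bool(catalog.table.at[g, "is_tf"])
            assert pd.isna(catalog.table.at[g, "sm_cluster_id"])

    def test_coordinates_non_overlapping_1_based(self, regulator_design):
        *_, catalog, _ = regulator_design
        t = catalog.table
        assert (t["start"] >= 1).all()
        assert (t["start"] <= t["end"]).all()
        for _, sub in t.groupby("chromosome"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()

    def test_zero_informant_fraction_empties_informant_set(self):
        spec = SyntheticSpec(n_genes=50, informant_fraction=0.0, seed=1)
        comp, truth = generate_compendium(spec)
        catalog = generate_catalog(spec, truth)
        assert catalog.informant_genes == set()

    def test_cluster_demand_beyond_supply_rejected(self):
        spec = SyntheticSpec(n_genes=12, n_sm_clusters=5,
                             sm_cluster_size_range=(5, 5), seed=0)
        with pytest.raises(ValueError, match="exceeds gene supply"):
            generate_compendium(spec)


class TestOntology:
    def test_acyclic_for_many_seeds(self):
        import networkx as nx

        for seed in range(1, 21):
            spec = SyntheticSpec(
                n_genes=40, modules=(ModuleSpec(10),), ontology_terms=25, seed=seed
            )
            _, truth = generate_compendium(spec)
            dag, _ = generate_ontology(spec, truth)
            assert nx.is_directed_acyclic_graph(dag.graph)
            assert len(dag.roots) == 1

    def test_depth_at_least_three(self, module_design):
        *_, dag, _, _ = module_design
        import networkx as nx

        root = dag.roots[0]
        depths = [
            nx.shortest_path_length(dag.graph, t, root)
            for t in dag.terms
            if nx.has_path(dag.graph, t, root)
        ]
        assert max(depths) >= 3

    def test_signature_terms_cover_their_modules(self, module_design):
        spec, _, truth, _, dag, annmap, _ = module_design
        for term, module in truth.term_to_module.items():
            members = truth.module_genes(module)
            covered = sum(term in annmap.direct.get(g, ()) for g in members)
            assert covered / len(members) >= 0.8
            background = [g for g in annmap.direct if truth.module_membership[g] != module]
            bg_rate = sum(term in annmap.direct[g] for g in background) / len(background)
            assert bg_rate <= spec.annotation_rate

    def test_root_annotates_everything_after_propagation(self, module_design):
        *_, dag, annmap, _ = module_design
        from coexnet.enrichment import propagate

        prop = propagate(annmap, dag)
        root = dag.roots[0]
        for g, terms in prop.propagated.items():
            if terms:
                assert root in terms

    def test_ontology_files_identical_across_runs(self, tmp_path):
        from coexnet.io import write_gaf, write_obo

        spec = SyntheticSpec(n_genes=30, modules=(ModuleSpec(10),),
                             ontology_terms=20, seed=6)
        _, truth = generate_compendium(spec)
        for i in (1, 2):
            dag, ann = generate_ontology(spec, truth)
            write_obo(dag, tmp_path / f"o{i}.obo")
            write_gaf(ann, tmp_path / f"a{i}.gaf")
        assert (tmp_path / "o1.obo").read_bytes() == (tmp_path / "o2.obo").read_bytes()
        assert (tmp_path / "a1.gaf").read_bytes() == (tmp_path / "a2.gaf").read_bytes()
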
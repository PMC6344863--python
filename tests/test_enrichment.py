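"""True-path propagation and Fisher-exact enrichment against an
arbitrary-precision hypergeometric oracle."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from coexnet.enrichment import enrich, enrich_subnetwork, propagate
from coexnet.io import AnnotationMap, build_ontology
from coexnet.subnetworks import extract_subnetwork


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact rational P[X >= k] for X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


@pytest.fixture()
def chain_dag():
    terms = {t: (t, "biological_process") for t in ["root", "mid", "leaf", "leaf2"]}
    return build_ontology(terms, [("mid", "root"), ("leaf", "mid"), ("leaf2", "mid")])


class TestPropagate:
    def test_ancestor_chain_closure(self, chain_dag):
        ann = AnnotationMap(direct={"g1": frozenset({"leaf"})})
        prop = propagate(ann, chain_dag)
        assert prop.propagated["g1"] == {"leaf", "mid", "root"}

    def test_idempotent(self, chain_dag):
        ann = AnnotationMap(direct={"g1": frozenset({"leaf"}), "g2": frozenset({"mid"})})
        once = propagate(ann, chain_dag)
        again = propagate(
            AnnotationMap(direct=once.propagated), chain_dag
        )
        assert again.propagated == once.propagated

    def test_unknown_terms_dropped_with_count(self, chain_dag):
        ann = AnnotationMap(direct={"g1": frozenset({"leaf", "bogus"})})
        prop = propagate(ann, chain_dag)
        assert prop.propagated["g1"] == {"leaf", "mid", "root"}
        assert prop.n_dropped_terms == 1

    def test_parent_counts_dominate_children(self, module_design):
        """After propagation, each term annotates at least as many genes as
        any of its children."""
        *_, dag, annmap, _ = module_design
        prop = propagate(annmap, dag)
        counts = {t: 0 for t in dag.terms}
        for terms in prop.propagated.values():
            for t in terms:
                counts[t] += 1
        for child, parent in dag.graph.edges:
            assert counts[parent] >= counts[child]


class TestEnrich:
    def test_study_equals_background_gives_p_one(self, chain_dag):
        genes = [f"g{i}" for i in range(20)]
        ann = AnnotationMap(direct={g: frozenset({"leaf"}) for g in genes[:7]})
        table = enrich(genes, genes, ann, chain_dag)
        assert (table["p_value"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_rational_oracle(self, chain_dag, seed):
        """Random study/background splits: scipy-based p equals the exact
        Fraction tail sum to 1e-10."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(50, 300))
        genes = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N // 2))
        n = int(rng.integers(1, N // 3))
        annotated = list(rng.choice(genes, size=K, replace=False))
        study = list(rng.choice(genes, size=n, replace=False))
        ann = AnnotationMap(direct={g: frozenset({"leaf"}) for g in annotated})
        table = enrich(study, genes, ann, chain_dag)
        row = table[table["term_id"] == "leaf"].iloc[0]
        exact = hypergeom_upper_tail(int(row["k"]), n, K, N)
        assert row["p_value"] == pytest.approx(float(exact), abs=1e-10)

    def test_documented_tail_example(self, chain_dag):
        """N=1000, K=50, n=10, k=5: p equals the direct tail sum."""
        genes = [f"g{i}" for i in range(1000)]
        annotated = set(genes[:50])
        study = genes[:5] + genes[50:55]  # k = 5 annotated of n = 10
        ann = AnnotationMap(direct={g: frozenset({"leaf"}) for g in annotated})
        table = enrich(study, genes, ann, chain_dag)
        row = table[table["term_id"] == "leaf"].iloc[0]
        assert int(row["k"]) == 5
        exact = float(hypergeom_upper_tail(5, 10, 50, 1000))
        assert row["p_value"] == pytest.approx(exact, abs=1e-10)

    def test_study_gene_missing_from_background_rejected(self, chain_dag):
        ann = AnnotationMap(direct={})
        with pytest.raises(ValueError, match="absent from background"):
            enrich(["gX"], ["g1", "g2"], ann, chain_dag)

    def test_bonferroni_never_more_enriched_than_uncorrected(self, module_design):
        _, compendium, truth, catalog, dag, annmap, corr = module_design
        prop = propagate(annmap, dag)
        background = catalog.gene_ids
        gene = truth.module_genes(0)[0]
        subnet = extract_subnetwork(corr, gene, 0.5)
        plain = enrich_subnetwork(subnet, background, prop, dag, correction="none")
        bonf = enrich_subnetwork(subnet, background, prop, dag, correction="bonferroni")
        assert bonf["enriched"].sum() <= plain["enriched"].sum()

    def test_root_term_never_significant_when_all_annotated(self, chain_dag):
        """When every background gene carries some annotation, propagation
        gives the root K = N, so its enrichment p is exactly 1 regardless of
        the study set."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        ann = AnnotationMap(direct={
            g: frozenset({rng.choice(["leaf", "leaf2"])}) for g in genes
        })
        study = list(rng.choice(genes, size=17, replace=False))
        table = enrich(study, genes, ann, chain_dag)
        root_row = table[table["term_id"] == "root"].iloc[0]
        assert root_row["K"] == root_row["N"]
        assert root_row["p_value"] == 1.0
        assert not root_row["enriched"]


class TestSubnetworkEnrichment:
    def test_signature_terms_enriched_in_module_subnetworks(self, module_design):
        """Each planted module's signature term reaches p < 0.05 in its
        members' sub-networks."""
        _, _, truth, catalog, dag, annmap, corr = module_design
        prop = propagate(annmap, dag)
        module_of_term = truth.term_to_module
        for term, module in module_of_term.items():
            gene = truth.module_genes(module)[0]
            subnet = extract_subnetwork(corr, gene, 0.5)
            table = enrich_subnetwork(subnet, catalog.gene_ids, prop, dag)
            p = table.loc[table["term_id"] == term, "p_value"].iloc[0]
            assert p < 0.05

    def test_sign_modes_partition_combined(self, module_design):
        _, _, truth, catalog, dag, annmap, corr = module_design
        prop = propagate(annmap, dag)
        gene = truth.module_genes(2)[0]  # mixed-sign module
        subnet = extract_subnetwork(corr, gene, 0.5)
        pos = {g for g, _ in subnet.positive_partners}
        neg = {g for g, _ in subnet.negative_partners}
        assert pos | neg == subnet.partner_genes
        assert not pos & neg
        combined = enrich_subnetwork(subnet, catalog.gene_ids, prop, dag, mode="combined")
        assert (combined["n"] == subnet.size).all()

    def test_empty_study_set_warns_and_returns_empty(self, module_design, chain_dag):
        from coexnet.subnetworks import SubNetwork

        subnet = SubNetwork(
            query_gene="q", cutoff=0.5,
            positive_partners=[("g1", 0.8)], negative_partners=[],
        )
        ann = AnnotationMap(direct={"g1": frozenset({"leaf"})})
        with pytest.warns(UserWarning, match="empty study set"):
            table = enrich_subnetwork(
                subnet, ["q", "g1"], ann, chain_dag, mode="negative_only"
            )
        assert table.empty
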
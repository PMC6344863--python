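"""GO term enrichment of sub-networks by one-sided Fisher's exact test.

Annotations are first propagated up the is_a DAG (true-path rule: a gene
annotated to a term is implicitly annotated to all its ancestors). For each
term with at least one annotated background gene, the upper-tail
hypergeometric probability of seeing k or more annotated genes in a study set
of size n, given K annotated among N background genes, is

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

which is the one-sided Fisher exact p-value for enrichment. The default
significance rule is uncorrected p < 0.05; a Bonferroni mode is provided.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal

import pandas as pd
from scipy.stats import hypergeom

from .io import AnnotationMap, OntologyDAG
from .subnetworks import SubNetwork

Correction = Literal["none", "bonferroni"]
Mode = Literal["combined", "positive_only", "negative_only"]


def propagate(annmap: AnnotationMap, dag: OntologyDAG) -> AnnotationMap:
    """Close each gene's term set under is_a ancestors (idempotent).

    Direct annotations to terms unknown to the DAG are dropped with a count.
    """
    dropped = 0
    known = set(dag.names)
    propagated: dict[str, frozenset[str]] = {}
    for gene, terms in annmap.direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in known:
                dropped += 1
                continue
            closed.add(t)
            closed |= dag.ancestors(t)
        propagated[gene] = frozenset(closed)
    return AnnotationMap(
        direct=annmap.direct,
        propagated=propagated,
        n_dropped_genes=annmap.n_dropped_genes,
        n_dropped_terms=dropped,
    )


def enrich(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    annmap: AnnotationMap,
    dag: OntologyDAG,
    alpha: float = 0.05,
    correction: Correction = "none",
) -> pd.DataFrame:
    """Test every term for over-representation in the study set.

    Returns a DataFrame (term_id, term_name, k, n, K, N, p_value,
    p_bonferroni, enriched) sorted by p_value; terms with no annotated
    background gene are excluded. The background must contain the study set;
    unannotated genes count toward N (the genome, not the annotated subset).
    """
    study = set(study_genes)
    background = set(background_genes)
    offenders = study - background
    if offenders:
        raise ValueError(
            f"study genes absent from background: {sorted(offenders)[:5]}"
        )
    if annmap.propagated is None:
        annmap = propagate(annmap, dag)

    n = len(study)
    N = len(background)
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in background:
        for t in annmap.terms_for(gene):
            term_K[t] = term_K.get(t, 0) + 1
            if gene in study:
                term_k[t] = term_k.get(t, 0) + 1

    rows = []
    for t, K in term_K.items():
        k = term_k.get(t, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(p, 0.0))
        rows.append((t, dag.names.get(t, t), k, n, K, N, p))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    m = len(table)
    table["p_bonferroni"] = (table["p_value"] * m).clip(upper=1.0)
    chosen = table["p_bonferroni"] if correction == "bonferroni" else table["p_value"]
    table["enriched"] = chosen < alpha
    table.attrs["alpha"] = alpha
    table.attrs["correction"] = correction
    return table.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)


def enrich_subnetwork(
    subnet: SubNetwork,
    background_genes: Iterable[str],
    annmap: AnnotationMap,
    dag: OntologyDAG,
    mode: Mode = "combined",
    alpha: float = 0.05,
    correction: Correction = "none",
) -> pd.DataFrame:
    """Enrichment of a sub-network's partner genes against the genome.

    ``mode`` selects the study set: all partners, positive partners only, or
    negative partners only. An empty study set returns an empty table with a
    warning.
    """
    if mode == "combined":
        study = subnet.partner_genes
    elif mode == "positive_only":
        study = {g for g, _ in subnet.positive_partners}
    elif mode == "negative_only":
        study = {g for g, _ in subnet.negative_partners}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not study:
        warnings.warn(
            f"empty study set for {subnet.query_gene} (mode={mode}): no enrichment"
        )
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "n", "K", "N", "p_value",
                     "p_bonferroni", "enriched"]
        )
    return enrich(study, background_genes, annmap, dag, alpha=alpha,
                  correction=correction)


def write_enrichment(table: pd.DataFrame, path, query: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        alpha = table.attrs.get("alpha", "")
        corr = table.attrs.get("correction", "")
        fh.write(f"# coexnet GO enrichment query={query} alpha={alpha} correction={corr}\n")
        table.to_csv(fh, sep="\t", index=False)
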
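"""Containers and readers/writers for the compendium, catalog, ontology and
annotations, plus replicate-to-condition collapse.

On-disk formats are the field's standards: TSV expression matrix (genes as
rows, arrays as columns), a two-column array-to-condition map, GFF3 gene
coordinates with a TSV attribute sidecar, OBO 1.2 ontologies and GAF 2.x
annotations. Reading goes through gffutils / obonet; validation is strict and
errors name the offending identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VERSION_COMMENT = "coexnet 0.1.0"


# ---------------------------------------------------------------------------
# expression compendium


@dataclass
class ExpressionCompendium:
    """Gene x array intensities (linear scale) with an array->condition map
    and, once collapsed, a gene x condition log2 matrix."""

    gene_ids: list[str]
    array_ids: list[str]
    array_to_condition: dict[str, str]
    intensities: pd.DataFrame  # genes x arrays, linear scale
    condition_log2: pd.DataFrame | None = None  # genes x conditions

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene id(s): {', '.join(dupes)}")
        if len(set(self.array_ids)) != len(self.array_ids):
            dupes = _duplicates(self.array_ids)
            raise ValueError(f"duplicate array id(s): {', '.join(dupes)}")
        missing = [a for a in self.array_ids if a not in self.array_to_condition]
        if missing:
            raise ValueError(f"array(s) without condition: {', '.join(missing)}")
        orphans = [a for a in self.array_to_condition if a not in set(self.array_ids)]
        if orphans:
            raise ValueError(
                f"condition map references absent array id(s): {', '.join(orphans)}"
            )
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite intensity values")
        if (vals < 0).any():
            bad = self.intensities.index[(vals < 0).any(axis=1)][0]
            raise ValueError(f"negative intensity for gene {bad}")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.array_ids:
            seen.setdefault(self.array_to_condition[a], None)
        return list(seen)

    @property
    def n_conditions(self) -> int:
        return len(set(self.array_to_condition.values()))


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_compendium(matrix_path, condition_map_path) -> ExpressionCompendium:
    """Read and validate a TSV expression matrix plus array->condition map.

    The returned compendium has ``condition_log2`` unset; call
    :func:`collapse_conditions` to fill it.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    cmap = pd.read_csv(
        condition_map_path, sep="\t", comment="#", dtype=str,
        names=["array_id", "condition"], header=0,
    )
    return ExpressionCompendium(
        gene_ids=list(matrix.index),
        array_ids=list(matrix.columns),
        array_to_condition=dict(zip(cmap["array_id"], cmap["condition"])),
        intensities=matrix,
    )


def collapse_conditions(
    compendium: ExpressionCompendium, pseudocount: float = 1.0
) -> ExpressionCompendium:
    """Fill ``condition_log2``: per-array log2, then arithmetic mean per condition.

    Each linear intensity v is mapped to log2(v + pseudocount), the
    pseudocount being applied only when the matrix contains any zero; each
    condition's value is the mean of its arrays' log2 values (log2-mean, the
    variance-stabilised convention — not mean-then-log). The result is
    invariant to array column order.
    """
    vals = compendium.intensities.to_numpy(dtype=float)
    pc = pseudocount if (vals == 0).any() else 0.0
    log2 = np.log2(vals + pc)
    log2df = pd.DataFrame(
        log2, index=compendium.intensities.index,
        columns=compendium.intensities.columns,
    )
    cond_order = compendium.conditions
    groups = {c: [] for c in cond_order}
    for a in compendium.array_ids:
        groups[compendium.array_to_condition[a]].append(a)
    collapsed = pd.DataFrame(
        {c: log2df[groups[c]].mean(axis=1) for c in cond_order},
        index=log2df.index,
    )
    compendium.condition_log2 = collapsed
    return compendium


def write_compendium(
    compendium: ExpressionCompendium, matrix_path, condition_map_path
) -> None:
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_VERSION_COMMENT} expression matrix (linear scale)\n")
        compendium.intensities.to_csv(fh, sep="\t", index_label="gene_id")
    with open(condition_map_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_VERSION_COMMENT} array-to-condition map\n")
        fh.write("array_id\tcondition\n")
        for a in compendium.array_ids:
            fh.write(f"{a}\t{compendium.array_to_condition[a]}\n")


# ---------------------------------------------------------------------------
# gene catalog

VALID_INFORMANT_CATEGORIES = {
    "none",
    "verified_Aniger",
    "verified_Anidulans",
    "verified_Afumigatus",
    "verified_Aoryzae",
    "sm_core",
}


@dataclass
class GeneCatalog:
    """Per-gene coordinates and functional flags.

    ``table`` is indexed by gene id with columns: chromosome, start, end,
    strand, is_tf, is_hypothetical, informant_category, sm_cluster_id,
    is_sm_core. Coordinates are 1-based inclusive (GFF3 convention).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate gene ids in catalog")
        if (t["start"] > t["end"]).any():
            bad = t.index[t["start"] > t["end"]][0]
            raise ValueError(f"start > end for gene {bad}")
        core_no_cluster = t["is_sm_core"] & t["sm_cluster_id"].isna()
        if core_no_cluster.any():
            raise ValueError(
                f"SM core without cluster id: {t.index[core_no_cluster][0]}"
            )
        bad_cat = ~t["informant_category"].isin(VALID_INFORMANT_CATEGORIES)
        if bad_cat.any():
            raise ValueError(
                f"unknown informant category {t.loc[bad_cat, 'informant_category'].iloc[0]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def informant_genes(self) -> set[str]:
        return set(self.table.index[self.table["informant_category"] != "none"])

    @property
    def tf_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_tf"]])

    @property
    def hypothetical_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_hypothetical"]])

    def informant_category(self, gene: str) -> str:
        return str(self.table.at[gene, "informant_category"])

    def clusters(self) -> dict[int, list[str]]:
        """cluster id -> member gene ids ordered by (chromosome, start)."""
        t = self.table[self.table["sm_cluster_id"].notna()]
        out: dict[int, list[str]] = {}
        for cid, sub in t.groupby("sm_cluster_id"):
            ordered = sub.sort_values(["chromosome", "start"])
            out[int(cid)] = list(ordered.index)
        return out


def write_catalog(catalog: GeneCatalog, gff3_path, attributes_path) -> None:
    """Emit GFF3 gene features plus the TSV flag sidecar."""
    t = catalog.table
    with open(gff3_path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g, row in t.iterrows():
            fh.write(
                f"{row['chromosome']}\tcoexnet\tgene\t{row['start']}\t{row['end']}\t"
                f".\t{row['strand']}\t.\tID={g}\n"
            )
    with open(attributes_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_VERSION_COMMENT} gene attributes\n")
        fh.write(
            "gene_id\tis_tf\tis_hypothetical\tinformant_category\t"
            "sm_cluster_id\tis_sm_core\n"
        )
        for g, row in t.iterrows():
            cid = "" if pd.isna(row["sm_cluster_id"]) else int(row["sm_cluster_id"])
            fh.write(
                f"{g}\t{int(row['is_tf'])}\t{int(row['is_hypothetical'])}\t"
                f"{row['informant_category']}\t{cid}\t{int(row['is_sm_core'])}\n"
            )


def read_catalog(gff3_path, attributes_path) -> GeneCatalog:
    """Read GFF3 gene coordinates (via gffutils) and the attribute sidecar."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    coords = {}
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ValueError(
                f"GFF3 gene at {feat.seqid}:{feat.start}-{feat.end} lacks ID"
            )
        gid = feat.attributes["ID"][0]
        coords[gid] = (feat.seqid, feat.start, feat.end, feat.strand or ".")

    attrs = pd.read_csv(
        attributes_path, sep="\t", comment="#", dtype={"gene_id": str},
    ).set_index("gene_id")
    rows = []
    for g, (chrom, start, end, strand) in coords.items():
        if g not in attrs.index:
            raise ValueError(f"gene {g} present in GFF3 but absent from attributes")
        a = attrs.loc[g]
        cid = a["sm_cluster_id"]
        rows.append(
            {
                "gene_id": g,
                "chromosome": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "is_tf": bool(int(a["is_tf"])),
                "is_hypothetical": bool(int(a["is_hypothetical"])),
                "informant_category": str(a["informant_category"]),
                "sm_cluster_id": None if pd.isna(cid) else int(cid),
                "is_sm_core": bool(int(a["is_sm_core"])),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return GeneCatalog(table=table)


# ---------------------------------------------------------------------------
# ontology + annotations


@dataclass
class OntologyDAG:
    """Rooted is_a DAG of ontology terms.

    ``graph`` is a networkx DiGraph with child -> parent edges; ``names`` and
    ``namespaces`` are keyed by term id.
    """

    graph: nx.DiGraph
    names: dict[str, str]
    namespaces: dict[str, str]
    _ancestors: dict[str, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if u not in self.names or v not in self.names:
                missing = u if u not in self.names else v
                raise ValueError(f"is_a edge to unknown term {missing}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    @property
    def terms(self) -> list[str]:
        return list(self.names)

    @property
    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (excluding itself)."""
        if self._ancestors is None:
            anc: dict[str, frozenset[str]] = {}
            # edges run child -> parent, so process parents first
            for t in reversed(list(nx.topological_sort(self.graph))):
                parents = list(self.graph.successors(t))
                s: set[str] = set(parents)
                for p in parents:
                    s |= anc[p]
                anc[t] = frozenset(s)
            self._ancestors = anc
        return self._ancestors[term]


def build_ontology(
    terms: Mapping[str, tuple[str, str]], is_a_edges: Iterable[tuple[str, str]]
) -> OntologyDAG:
    """Assemble an OntologyDAG from {term: (name, namespace)} and child->parent edges."""
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(is_a_edges)
    return OntologyDAG(
        graph=g,
        names={t: n for t, (n, _) in terms.items()},
        namespaces={t: ns for t, (_, ns) in terms.items()},
    )


def write_obo(dag: OntologyDAG, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: coexnet-synthetic\n")
        for t in dag.terms:
            fh.write("\n[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.names[t]}\n")
            fh.write(f"namespace: {dag.namespaces[t]}\n")
            for parent in sorted(dag.graph.successors(t)):
                fh.write(f"is_a: {parent} ! {dag.names[parent]}\n")


def read_ontology(obo_path, namespace: str | None = "biological_process") -> OntologyDAG:
    """Read an OBO 1.2 file (via obonet), keeping is_a edges only.

    Terms are restricted to ``namespace`` by default (biological_process);
    pass ``namespace=None`` to keep all.
    """
    import obonet

    g = obonet.read_obo(str(obo_path))
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for t, data in g.nodes(data=True):
        ns = data.get("namespace", "")
        if namespace is not None and ns != namespace:
            continue
        names[t] = data.get("name", t)
        namespaces[t] = ns
    edges = []
    for u, v, key in g.edges(keys=True):
        if key != "is_a":
            continue
        if u in names and v not in names:
            raise ValueError(f"is_a edge from {u} to unknown term {v}")
        if u in names and v in names:
            edges.append((u, v))
    return build_ontology(
        {t: (names[t], namespaces[t]) for t in names}, edges
    )


@dataclass
class AnnotationMap:
    """Gene -> GO term sets: direct assignments and (optionally) the
    true-path propagated closure."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] | None = None
    n_dropped_genes: int = 0
    n_dropped_terms: int = 0

    def terms_for(self, gene: str) -> frozenset[str]:
        source = self.propagated if self.propagated is not None else self.direct
        return source.get(gene, frozenset())


def write_gaf(annmap: AnnotationMap, path) -> None:
    """Emit direct annotations as GAF 2.1 (gene id in column 2, term in 5)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in annmap.direct:
            for term in sorted(annmap.direct[gene]):
                cols = [
                    "SYN", gene, gene, "", term, "SYN_REF:0000001", "IEA", "",
                    "P", "", "", "gene", "taxon:0", "20160302", "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def read_annotations(gaf_path, catalog: GeneCatalog) -> AnnotationMap:
    """Read a GAF 2.x file; rows for genes absent from the catalog are dropped
    (with a logged count) and duplicate gene+term rows collapse to one."""
    known = set(catalog.gene_ids)
    direct: dict[str, set[str]] = {}
    dropped = 0
    with open(gaf_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            gene, term = cols[1], cols[4]
            if gene not in known:
                dropped += 1
                continue
            direct.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("dropped %d GAF rows for genes absent from catalog", dropped)
    return AnnotationMap(
        direct={g: frozenset(ts) for g, ts in direct.items()},
        n_dropped_genes=dropped,
    )
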
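"""Secondary-metabolite cluster expression survey and trans-regulator scan.

Fungal secondary-metabolite (SM) pathways are encoded in contiguous gene
clusters anchored by a core synthase/synthetase (PKS/NRPS). Three questions
are asked of the co-expression compendium:

1. Is each core gene *expressed* anywhere in the compendium (above a floor in
   at least one condition)?
2. Is the cluster *coherent* — are its non-core members co-expressed with a
   core, and is any physically embedded transcription factor?
3. Which TF / chromatin-regulator genes located *outside* every cluster are
   co-expressed with many core genes — candidate global (trans-acting)
   regulators of secondary metabolism?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationResult, spearman_rho
from .io import ExpressionCompendium, GeneCatalog


@dataclass
class SMCluster:
    """One contiguous SM cluster: members in coordinate order, its core
    (PKS/NRPS-type) genes, and any embedded TFs."""

    cluster_id: int
    member_genes: list[str]
    core_genes: list[str]
    embedded_tfs: list[str]


@dataclass
class ClusterReport:
    cluster_id: int
    evaluable: bool
    core_expressed: bool
    member_coexpression_fraction: float
    contiguous_tf_coexpressed: bool


@dataclass
class RegulatorCandidate:
    gene: str
    n_cores_positive: int
    n_cores_negative: int

    @property
    def n_cores_total(self) -> int:
        return self.n_cores_positive + self.n_cores_negative

    @property
    def pattern(self) -> str:
        if self.n_cores_positive and self.n_cores_negative:
            return "positive_and_negative"
        if self.n_cores_negative:
            return "negative_only"
        return "positive_only"


def clusters_from_catalog(catalog: GeneCatalog) -> list[SMCluster]:
    """Assemble SMCluster records from catalog flags, validating contiguity."""
    t = catalog.table
    out = []
    for cid, members in catalog.clusters().items():
        rows = t.loc[members]
        if rows["chromosome"].nunique() != 1:
            raise ValueError(f"SM cluster {cid} spans chromosomes")
        chrom = rows["chromosome"].iloc[0]
        on_chrom = t[t["chromosome"] == chrom].sort_values("start")
        idx = [on_chrom.index.get_loc(g) for g in members]
        if sorted(idx) != list(range(min(idx), max(idx) + 1)):
            raise ValueError(f"SM cluster {cid} is not a contiguous coordinate run")
        cores = [g for g in members if t.at[g, "is_sm_core"]]
        if not cores:
            raise ValueError(f"SM cluster {cid} has no core gene")
        tfs = [g for g in members if t.at[g, "is_tf"]]
        out.append(SMCluster(cid, members, cores, tfs))
    return sorted(out, key=lambda c: c.cluster_id)


def core_expression_survey(
    compendium: ExpressionCompendium,
    clusters: list[SMCluster],
    floor: float | None = None,
) -> dict[str, bool]:
    """Flag each core gene expressed iff it exceeds the floor in >= 1 condition.

    ``floor`` defaults to the 20th percentile of all gene-by-condition log2
    values — a platform-free surrogate for a microarray present call, and
    monotone-invariant like the rest of the pipeline.
    """
    if compendium.condition_log2 is None:
        raise ValueError("condition_log2 not filled; run collapse_conditions first")
    mat = compendium.condition_log2
    if floor is None:
        floor = float(np.percentile(mat.to_numpy(), 20))
    flags: dict[str, bool] = {}
    for cl in clusters:
        for core in cl.core_genes:
            if core not in mat.index:
                warnings.warn(f"SM core {core} absent from compendium: unexpressed")
                flags[core] = False
                continue
            flags[core] = bool((mat.loc[core].to_numpy() > floor).any())
    return flags


def cluster_coherence(
    corr: CorrelationResult,
    clusters: list[SMCluster],
    cutoff: float = 0.5,
    expressed: dict[str, bool] | None = None,
) -> list[ClusterReport]:
    """Per-cluster co-expression coherence against the core gene(s).

    ``member_coexpression_fraction`` is the fraction of non-core members with
    |rho| >= cutoff to a core (max over cores when several exist);
    ``contiguous_tf_coexpressed`` asks the same of embedded TFs. Clusters with
    no valid core are marked not evaluable.
    """
    if cutoff < corr.report_threshold:
        raise ValueError(
            f"cutoff {cutoff} below report threshold {corr.report_threshold}"
        )
    adj = corr.adjacency()
    reports = []
    for cl in clusters:
        cores = [c for c in cl.core_genes if c in corr.valid_genes]
        core_expressed = (
            any(expressed.get(c, False) for c in cl.core_genes)
            if expressed is not None
            else bool(cores)
        )
        if not cores:
            reports.append(ClusterReport(cl.cluster_id, False, core_expressed, 0.0, False))
            continue
        linked: set[str] = set()
        for core in cores:
            for partner, rho in adj[core]:
                if abs(rho) >= cutoff:
                    linked.add(partner)
        non_core = [g for g in cl.member_genes if g not in cl.core_genes]
        frac = (
            sum(g in linked for g in non_core) / len(non_core) if non_core else 0.0
        )
        tf_hit = any(tf in linked for tf in cl.embedded_tfs)
        reports.append(ClusterReport(cl.cluster_id, True, core_expressed, frac, tf_hit))
    return reports


def contiguous_tf_fraction(reports: list[ClusterReport]) -> float:
    """Genome-wide fraction of evaluable clusters whose embedded TF is
    co-expressed with a core."""
    evaluable = [r for r in reports if r.evaluable]
    if not evaluable:
        return 0.0
    return sum(r.contiguous_tf_coexpressed for r in evaluable) / len(evaluable)


def scan_trans_regulators(
    corr: CorrelationResult,
    catalog: GeneCatalog,
    cutoff: float = 0.5,
    min_cores: int = 2,
) -> list[RegulatorCandidate]:
    """Rank out-of-cluster TF / chromatin-regulator genes by how many SM core
    genes they are co-expressed with at ``cutoff``.

    Only flagged genes residing outside every cluster are scored (a
    pathway-specific in-cluster TF is a different object). Candidates with
    fewer than ``min_cores`` correlated cores are dropped; ties in total core
    count break by gene id, so the ranking is independent of catalog row
    order.
    """
    if cutoff < corr.report_threshold:
        raise ValueError(
            f"cutoff {cutoff} below report threshold {corr.report_threshold}"
        )
    t = catalog.table
    cores = set(t.index[t["is_sm_core"]])
    if not cores:
        raise ValueError("catalog defines no SM core genes")
    flagged = sorted(
        g for g in t.index[t["is_tf"]] if pd.isna(t.at[g, "sm_cluster_id"])
    )
    if not flagged:
        warnings.warn("no out-of-cluster TF/chromatin-regulator genes flagged")
        return []
    adj = corr.adjacency()
    candidates = []
    for g in flagged:
        if g not in corr.valid_genes:
            continue
        n_pos = n_neg = 0
        for partner, rho in adj[g]:
            if partner in cores:
                if rho >= cutoff:
                    n_pos += 1
                elif rho <= -cutoff:
                    n_neg += 1
        if n_pos + n_neg >= min_cores:
            candidates.append(RegulatorCandidate(g, n_pos, n_neg))
    candidates.sort(key=lambda c: (-c.n_cores_total, c.gene))
    return candidates


def regulator_pair_correlation(
    compendium: ExpressionCompendium, gene_a: str, gene_b: str
) -> float:
    """Spearman rho between two genes' condition-level profiles."""
    if compendium.condition_log2 is None:
        raise ValueError("condition_log2 not filled; run collapse_conditions first")
    mat = compendium.condition_log2
    for g in (gene_a, gene_b):
        if g not in mat.index:
            raise KeyError(f"gene {g} absent from compendium")
    return spearman_rho(mat.loc[gene_a].to_numpy(), mat.loc[gene_b].to_numpy())


def sm_core_component(
    corr: CorrelationResult, catalog: GeneCatalog, cutoff: float = 0.5
) -> set[str]:
    """Largest connected component of the thresholded network touching SM cores.

    A convenience view of the "large SM sub-network": genes connected (via
    edges at |rho| >= cutoff) to the component containing the most SM core
    genes.
    """
    cores = set(catalog.table.index[catalog.table["is_sm_core"]])
    g = nx.Graph()
    for a, b, r in corr.edges.itertuples(index=False):
        if abs(r) >= cutoff:
            g.add_edge(a, b)
    best: set[str] = set()
    best_cores = -1
    for comp in nx.connected_components(g):
        n_cores = len(comp & cores)
        if n_cores > best_cores:
            best, best_cores = set(comp), n_cores
    return best


def write_cluster_report(reports: list[ClusterReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# coexnet SM cluster report; contiguous_tf_fraction="
            f"{contiguous_tf_fraction(reports):.4f}\n"
        )
        fh.write(
            "cluster_id\tevaluable\tcore_expressed\tmember_coexpression_fraction\t"
            "contiguous_tf_coexpressed\n"
        )
        for r in reports:
            fh.write(
                f"{r.cluster_id}\t{int(r.evaluable)}\t{int(r.core_expressed)}\t"
                f"{r.member_coexpression_fraction:.4f}\t{int(r.contiguous_tf_coexpressed)}\n"
            )


def write_regulator_candidates(candidates: list[RegulatorCandidate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# coexnet trans-regulator candidates\n")
        fh.write("rank\tgene\tn_cores_positive\tn_cores_negative\tpattern\n")
        for i, c in enumerate(candidates, 1):
            fh.write(
                f"{i}\t{c.gene}\t{c.n_cores_positive}\t{c.n_cores_negative}\t{c.pattern}\n"
            )
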
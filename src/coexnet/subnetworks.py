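"""Per-gene co-expression sub-networks at dual stringencies.

A query gene's sub-network is the set of partners whose |rho| with it meets a
stringency cutoff, split into positively and negatively correlated lists
(guilt-by-association works through both signs). The two conventional
stringencies are |0.5| ("stringent") and |0.7| ("highly stringent").
Prioritized overlays restrict a sub-network to informant ORFs — genes with
wet-lab validation in an Aspergillus species or predicted SM core enzymes —
which carry functional evidence onto unknown partners.
"""

from __future__ import annotations

from dataclasses import dataclass

from .correlation import CorrelationResult
from .io import GeneCatalog

STRINGENT = 0.5
HIGHLY_STRINGENT = 0.7


@dataclass
class SubNetwork:
    """One query gene's partners at a stringency cutoff, split by sign and
    sorted by |rho| descending."""

    query_gene: str
    cutoff: float
    positive_partners: list[tuple[str, float]]
    negative_partners: list[tuple[str, float]]

    @property
    def size(self) -> int:
        return len(self.positive_partners) + len(self.negative_partners)

    @property
    def partner_genes(self) -> set[str]:
        return {g for g, _ in self.positive_partners} | {
            g for g, _ in self.negative_partners
        }


@dataclass
class PrioritizedSubNetwork:
    """A sub-network filtered to informant partners, with categories attached."""

    query_gene: str
    cutoff: float
    informant_partners: list[tuple[str, float, str]]  # (gene, rho, category)

    @property
    def size(self) -> int:
        return len(self.informant_partners)


def extract_subnetwork(
    corr: CorrelationResult, gene: str, cutoff: float = STRINGENT
) -> SubNetwork:
    """Partners of ``gene`` with |rho| >= cutoff, partitioned by sign."""
    if cutoff < corr.report_threshold:
        raise ValueError(
            f"cutoff {cutoff} below report threshold {corr.report_threshold}"
        )
    if gene not in corr.valid_genes:
        if gene in corr.gene_ids:
            raise KeyError(f"gene {gene} has a constant profile (rho undefined)")
        raise KeyError(f"gene {gene} absent from correlation result")
    partners = [(p, r) for p, r in corr.adjacency()[gene] if abs(r) >= cutoff]
    partners.sort(key=lambda pr: (-abs(pr[1]), pr[0]))
    return SubNetwork(
        query_gene=gene,
        cutoff=cutoff,
        positive_partners=[(p, r) for p, r in partners if r > 0],
        negative_partners=[(p, r) for p, r in partners if r < 0],
    )


def prioritize(subnet: SubNetwork, catalog: GeneCatalog) -> PrioritizedSubNetwork:
    """Restrict a sub-network to informant ORF partners."""
    informants = catalog.informant_genes
    kept = [
        (g, r, catalog.informant_category(g))
        for g, r in subnet.positive_partners + subnet.negative_partners
        if g in informants
    ]
    kept.sort(key=lambda t: (-abs(t[1]), t[0]))
    return PrioritizedSubNetwork(
        query_gene=subnet.query_gene, cutoff=subnet.cutoff, informant_partners=kept
    )


def network_summary(
    corr: CorrelationResult, cutoff: float, catalog: GeneCatalog | None = None
) -> dict[str, int | float]:
    """Global headline counts of the thresholded network at ``cutoff``.

    Reports the number of genes with at least one partner (the "gene
    networks" count), signed edge counts, and — when a catalog is supplied —
    how many query genes have an informant partner and how many hypothetical
    genes have any partner.
    """
    if cutoff < corr.report_threshold:
        raise ValueError(
            f"cutoff {cutoff} below report threshold {corr.report_threshold}"
        )
    n_pos, n_neg = corr.n_pairs_signed(cutoff)
    degree: dict[str, int] = {}
    informant_partnered: set[str] = set()
    informants = catalog.informant_genes if catalog is not None else set()
    for a, b, r in corr.edges.itertuples(index=False):
        if abs(r) < cutoff:
            continue
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
        if b in informants:
            informant_partnered.add(a)
        if a in informants:
            informant_partnered.add(b)
    summary: dict[str, int | float] = {
        "cutoff": cutoff,
        "n_gene_networks": len(degree),
        "n_edges_positive": n_pos,
        "n_edges_negative": n_neg,
        "n_edges_total": n_pos + n_neg,
    }
    if catalog is not None:
        summary["n_genes_with_informant_partner"] = len(informant_partnered)
        summary["n_hypothetical_with_partner"] = len(
            catalog.hypothetical_genes & set(degree)
        )
    return summary


def subnetwork_to_tsv(
    subnet: SubNetwork, catalog: GeneCatalog | None, path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# coexnet sub-network query={subnet.query_gene} cutoff={subnet.cutoff}\n")
        fh.write("partner_gene\trho\tsign\tinformant_category\tis_tf\tis_hypothetical\n")
        for plist, sign in ((subnet.positive_partners, "+"), (subnet.negative_partners, "-")):
            for g, r in plist:
                if catalog is not None and g in catalog.table.index:
                    cat = catalog.informant_category(g)
                    tf = int(bool(catalog.table.at[g, "is_tf"]))
                    hyp = int(bool(catalog.table.at[g, "is_hypothetical"]))
                else:
                    cat, tf, hyp = "none", 0, 0
                fh.write(f"{g}\t{r:.6f}\t{sign}\t{cat}\t{tf}\t{hyp}\n")
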
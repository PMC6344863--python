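"""End-to-end orchestration: simulate/read -> collapse -> calibrate ->
all-pairs -> sub-networks -> prioritized overlays -> enrichment -> landscape
-> SM survey and regulator scan, with a JSON run manifest.

Rerunning with an identical configuration reproduces byte-identical outputs
(all randomness flows from the configured seeds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as cio
from . import landscape as clandscape
from . import smclusters as sm
from .correlation import DEFAULT_CANDIDATES, all_pairs, calibrate_threshold
from .enrichment import enrich_subnetwork, propagate, write_enrichment
from .subnetworks import (
    HIGHLY_STRINGENT,
    STRINGENT,
    extract_subnetwork,
    network_summary,
    prioritize,
    subnetwork_to_tsv,
)
from .synthetic import SyntheticSpec, generate_catalog, generate_compendium, generate_ontology, write_artifacts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, cutoffs and scan parameters for one full run."""

    outdir: str
    # either a synthetic spec ...
    synthetic: SyntheticSpec | None = None
    # ... or paths to on-disk inputs
    matrix_path: str | None = None
    condition_map_path: str | None = None
    gff3_path: str | None = None
    attributes_path: str | None = None
    obo_path: str | None = None
    gaf_path: str | None = None

    stringent_cutoff: float = STRINGENT
    highly_stringent_cutoff: float = HIGHLY_STRINGENT
    calibration_candidates: tuple[float, ...] = DEFAULT_CANDIDATES
    calibration_seed: int = 0
    alpha: float = 0.05
    correction: str = "none"
    enrichment_mode: str = "combined"
    enrichment_queries: tuple[str, ...] = ()  # per-gene outputs are by request
    subnetwork_queries: tuple[str, ...] = ()
    sm_min_cores: int = 2
    sm_expression_floor: float | None = None

    def validate(self) -> None:
        if self.stringent_cutoff > self.highly_stringent_cutoff:
            raise ValueError(
                "stringent cutoff must be <= highly stringent cutoff "
                f"({self.stringent_cutoff} > {self.highly_stringent_cutoff})"
            )
        if self.synthetic is None:
            needed = [self.matrix_path, self.condition_map_path, self.gff3_path,
                      self.attributes_path, self.obo_path, self.gaf_path]
            if any(p is None for p in needed):
                raise ValueError("either a synthetic spec or all six input paths required")
            for p in needed:
                if not Path(p).exists():
                    raise FileNotFoundError(p)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": "0.1.0", "stages": {}, "parameters": {
        "stringent_cutoff": config.stringent_cutoff,
        "highly_stringent_cutoff": config.highly_stringent_cutoff,
        "calibration_seed": config.calibration_seed,
        "alpha": config.alpha,
        "correction": config.correction,
        "sm_min_cores": config.sm_min_cores,
    }}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # --- inputs ------------------------------------------------------------
    if config.synthetic is not None:
        rec = stage("simulate")
        compendium, truth = generate_compendium(config.synthetic)
        catalog = generate_catalog(config.synthetic, truth)
        dag, annmap = generate_ontology(config.synthetic, truth)
        paths = write_artifacts(outdir / "inputs", compendium, catalog, dag, annmap)
        rec.update(paths)
        rec["seed"] = config.synthetic.seed
        manifest["parameters"]["synthetic_seed"] = config.synthetic.seed
    else:
        rec = stage("read")
        compendium = cio.read_compendium(config.matrix_path, config.condition_map_path)
        catalog = cio.read_catalog(config.gff3_path, config.attributes_path)
        dag = cio.read_ontology(config.obo_path)
        annmap = cio.read_annotations(config.gaf_path, catalog)
        rec["n_genes"] = len(compendium.gene_ids)
        rec["n_arrays"] = len(compendium.array_ids)

    # --- collapse ----------------------------------------------------------
    rec = stage("collapse")
    cio.collapse_conditions(compendium)
    cond_path = outdir / "condition_log2.tsv"
    with open(cond_path, "w", encoding="utf-8") as fh:
        fh.write("# coexnet condition-level log2 matrix\n")
        compendium.condition_log2.to_csv(fh, sep="\t", index_label="gene_id")
    rec["path"] = str(cond_path)
    rec["n_conditions"] = compendium.n_conditions

    # --- calibration -------------------------------------------------------
    rec = stage("calibrate")
    calibration = calibrate_threshold(
        compendium.condition_log2,
        candidates=config.calibration_candidates,
        seed=config.calibration_seed,
    )
    cal_path = outdir / "calibration.tsv"
    calibration.to_tsv(cal_path)
    rec["path"] = str(cal_path)
    rec["chosen_threshold"] = calibration.chosen_threshold
    rec["exceedance_counts"] = {str(k): v for k, v in calibration.exceedance_counts.items()}
    if not calibration.calibrated:
        logger.warning("null calibration chose no threshold; using configured cutoffs")

    # --- all pairs ---------------------------------------------------------
    rec = stage("correlate")
    corr = all_pairs(compendium.condition_log2, report_threshold=config.stringent_cutoff)
    edges_path = outdir / "edges.tsv"
    corr.to_tsv(edges_path)
    rec["path"] = str(edges_path)
    rec["n_valid_genes"] = len(corr.valid_genes)
    rec["n_edges"] = len(corr.edges)

    # --- network summaries + sub-networks ----------------------------------
    rec = stage("subnetworks")
    summaries = [
        network_summary(corr, cutoff, catalog)
        for cutoff in (config.stringent_cutoff, config.highly_stringent_cutoff)
    ]
    summary_path = outdir / "network_summary.tsv"
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write("# coexnet network summary\n")
        keys = list(summaries[0])
        fh.write("\t".join(keys) + "\n")
        for s in summaries:
            fh.write("\t".join(str(s[k]) for k in keys) + "\n")
    rec["summary_path"] = str(summary_path)
    rec["summaries"] = summaries

    # per-gene sub-network sizes at both stringencies (always covers all genes)
    sizes_path = outdir / "subnetwork_sizes.tsv"
    adj = corr.adjacency()
    with open(sizes_path, "w", encoding="utf-8") as fh:
        fh.write("# coexnet per-gene sub-network sizes\n")
        fh.write("gene_id\tn_partners_stringent\tn_partners_highly_stringent\t"
                 "n_informant_partners_stringent\n")
        informants = catalog.informant_genes
        for g in corr.gene_ids:
            partners = adj.get(g, [])
            n_s = sum(abs(r) >= config.stringent_cutoff for _, r in partners)
            n_h = sum(abs(r) >= config.highly_stringent_cutoff for _, r in partners)
            n_i = sum(
                p in informants
                for p, r in partners
                if abs(r) >= config.stringent_cutoff
            )
            fh.write(f"{g}\t{n_s}\t{n_h}\t{n_i}\n")
    rec["sizes_path"] = str(sizes_path)

    # per-query emission is by request (bounded output volume)
    query_dir = outdir / "subnetworks"
    for q in config.subnetwork_queries:
        query_dir.mkdir(exist_ok=True)
        subnet = extract_subnetwork(corr, q, config.stringent_cutoff)
        subnetwork_to_tsv(subnet, catalog, query_dir / f"{q}.tsv")
        pri = prioritize(subnet, catalog)
        with open(query_dir / f"{q}.prioritized.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# coexnet prioritized sub-network query={q}\n")
            fh.write("partner_gene\trho\tinformant_category\n")
            for g2, r, cat in pri.informant_partners:
                fh.write(f"{g2}\t{r:.6f}\t{cat}\n")
    if config.subnetwork_queries:
        rec["query_dir"] = str(query_dir)

    # --- enrichment --------------------------------------------------------
    rec = stage("enrichment")
    annmap = propagate(annmap, dag)
    background = [g for g in catalog.gene_ids if g in set(compendium.gene_ids)]
    for q in config.enrichment_queries:
        subnet = extract_subnetwork(corr, q, config.stringent_cutoff)
        table = enrich_subnetwork(
            subnet, background, annmap, dag, mode=config.enrichment_mode,
            alpha=config.alpha, correction=config.correction,
        )
        path = outdir / f"enrichment_{q}.tsv"
        write_enrichment(table, path, query=q)
        rec[q] = {"path": str(path), "n_terms": len(table),
                  "n_enriched": int(table["enriched"].sum()) if len(table) else 0}

    # --- landscape ---------------------------------------------------------
    rec = stage("landscape")
    profile = clandscape.classify_loci(
        clandscape.chromosomal_landscape(compendium, catalog)
    )
    land_path = outdir / "landscape.tsv"
    clandscape.write_landscape(profile, land_path)
    rec["path"] = str(land_path)
    rec["class_counts"] = profile["expression_class"].value_counts().to_dict()

    # --- SM survey and regulator scan --------------------------------------
    rec = stage("sm_scan")
    clusters = sm.clusters_from_catalog(catalog)
    if clusters:
        expressed = sm.core_expression_survey(
            compendium, clusters, floor=config.sm_expression_floor
        )
        reports = sm.cluster_coherence(
            corr, clusters, config.stringent_cutoff, expressed=expressed
        )
        rep_path = outdir / "sm_cluster_report.tsv"
        sm.write_cluster_report(reports, rep_path)
        candidates = sm.scan_trans_regulators(
            corr, catalog, config.stringent_cutoff, min_cores=config.sm_min_cores
        )
        cand_path = outdir / "regulator_candidates.tsv"
        sm.write_regulator_candidates(candidates, cand_path)
        rec["cluster_report"] = str(rep_path)
        rec["regulator_candidates"] = str(cand_path)
        rec["n_clusters"] = len(clusters)
        rec["n_cores_expressed"] = sum(expressed.values())
        rec["contiguous_tf_fraction"] = sm.contiguous_tf_fraction(reports)
        rec["n_regulator_candidates"] = len(candidates)
    else:
        rec["n_clusters"] = 0

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
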
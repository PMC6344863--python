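"""Synthetic expression compendia with planted, recoverable structure.

Every downstream stage of the pipeline (correlation thresholding, sub-network
extraction, GO enrichment, secondary-metabolite scans) is validated against
data where the truth is known by construction. The generator plants:

* **co-expression modules** — each module shares one latent factor per
  condition (standard normal); member genes load on it with tunable mean,
  spread and a fraction of negative signs, giving mixed-sign Spearman
  structure of controllable strength on top of log-normal baselines;
* **replicate arrays** — condition-level log2 values are observed through
  replicate arrays with small independent array noise, so replicate collapse
  is exercised nontrivially (default layout: 283 arrays over 155 conditions);
* **secondary-metabolite clusters** — contiguous coordinate runs, one core
  (PKS/NRPS-like) gene each, optionally an embedded pathway TF;
* **trans-regulators** — TF-flagged genes outside every cluster that share a
  dedicated latent factor with all SM core genes, emulating global regulators
  of secondary metabolism;
* **an ontology** — a rooted is_a DAG whose per-module "signature" leaf terms
  annotate most module members and few background genes, so enrichment has a
  planted positive control.

Because Spearman correlation is invariant to the monotone map 2^x, targets
set on the log2 scale hold identically on the emitted linear-scale matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    ExpressionCompendium,
    GeneCatalog,
    OntologyDAG,
    build_ontology,
)

INFORMANT_CATEGORIES = (
    "verified_Aniger",
    "verified_Anidulans",
    "verified_Afumigatus",
    "verified_Aoryzae",
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    loading_mean: float = 1.5
    loading_sd: float = 0.3
    negative_fraction: float = 0.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study; defaults emulate the 155-condition,
    283-array Aspergillus compendium geometry."""

    n_genes: int = 1000
    n_conditions: int = 155
    # int -> same count per condition; None -> 283-array layout when
    # n_conditions == 155 (128 duplicated + 27 singleton conditions), else 2.
    replicates_per_condition: int | Sequence[int] | None = None
    modules: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 0.5  # log2-scale residual sd per gene x condition
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    array_noise_sd: float = 0.1  # log2-scale replicate-array noise
    n_sm_clusters: int = 0
    sm_cluster_size_range: tuple[int, int] = (4, 8)
    sm_clusters_on_modules: bool = False
    tf_embedded_fraction: float = 0.3
    n_planted_regulators: int = 0
    regulator_loading_mean: float = 1.5
    regulator_loading_sd: float = 0.1
    core_negative_fraction: float = 0.0
    tf_fraction: float = 0.05
    informant_fraction: float = 0.1
    hypothetical_fraction: float = 0.4
    ontology_terms: int = 30
    annotation_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(m.size for m in self.modules)} "
                f"> n_genes={self.n_genes}"
            )
        for name in (
            "tf_fraction",
            "informant_fraction",
            "hypothetical_fraction",
            "annotation_rate",
            "tf_embedded_fraction",
            "core_negative_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} not in [0, 1]")
        for m in self.modules:
            if not (0.0 <= m.negative_fraction <= 1.0):
                raise ValueError("module negative_fraction not in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.sm_cluster_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid sm_cluster_size_range")
        if self.sm_clusters_on_modules and self.n_planted_regulators:
            raise ValueError(
                "sm_clusters_on_modules and planted regulators are mutually "
                "exclusive: each gene loads on at most one latent factor"
            )
        if self.sm_clusters_on_modules and self.n_sm_clusters > len(self.modules):
            raise ValueError("more SM clusters than modules to place them on")

    def replicate_counts(self) -> list[int]:
        r = self.replicates_per_condition
        if r is None:
            if self.n_conditions == 155:
                return [2] * 128 + [1] * 27  # 283 arrays
            return [2] * self.n_conditions
        if isinstance(r, int):
            return [r] * self.n_conditions
        r = list(r)
        if len(r) != self.n_conditions:
            raise ValueError("per-condition replicate list length mismatch")
        return r


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    module_membership: dict[str, int | None]
    loading_signs: dict[str, str]  # '+' or '-' for module/program genes
    planted_regulator_ids: list[str]
    term_to_module: dict[str, int]
    sm_cluster_members: dict[int, list[str]] = field(default_factory=dict)
    sm_core_ids: list[str] = field(default_factory=list)
    embedded_tf_ids: list[str] = field(default_factory=list)
    baseline_log2: dict[str, float] = field(default_factory=dict)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


@dataclass(frozen=True)
class _Layout:
    module_ranges: list[range]
    regulator_indices: list[int]
    cluster_ranges: dict[int, range]
    core_indices: dict[int, int]
    embedded_tf_indices: dict[int, int]


def _layout(spec: SyntheticSpec) -> _Layout:
    """Deterministic placement of modules, regulators and SM clusters on the
    gene index line, shared by compendium and catalog generation."""
    module_ranges = []
    cursor = 0
    for m in spec.modules:
        module_ranges.append(range(cursor, cursor + m.size))
        cursor += m.size
    regulator_indices = list(range(cursor, cursor + spec.n_planted_regulators))
    cursor += spec.n_planted_regulators

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    lo, hi = spec.sm_cluster_size_range
    cluster_ranges: dict[int, range] = {}
    core_indices: dict[int, int] = {}
    embedded_tf_indices: dict[int, int] = {}
    n_embedded = round(spec.tf_embedded_fraction * spec.n_sm_clusters)
    for c in range(spec.n_sm_clusters):
        size = int(rng.integers(lo, hi + 1))
        if spec.sm_clusters_on_modules:
            base = module_ranges[c]
            if size > len(base):
                size = len(base)
            run = range(base.start, base.start + size)
        else:
            if cursor + size > spec.n_genes:
                raise ValueError(
                    f"SM cluster demand exceeds gene supply at cluster {c}: "
                    f"need {size} genes beyond index {cursor} of {spec.n_genes}"
                )
            run = range(cursor, cursor + size)
            cursor += size
        cluster_ranges[c] = run
        core_indices[c] = run.start  # first gene of the run is the core
        if c < n_embedded and len(run) >= 2:
            embedded_tf_indices[c] = run.start + 1
    return _Layout(
        module_ranges, regulator_indices, cluster_ranges, core_indices,
        embedded_tf_indices,
    )


def generate_compendium(spec: SyntheticSpec) -> tuple[ExpressionCompendium, GroundTruth]:
    """Simulate the expression compendium and return it with its ground truth.

    Condition-level model: gene g in module m has log2 value
    ``baseline_g + a_g * f_mc + eps`` with per-condition latent factor
    ``f_mc ~ N(0,1)``, loading ``a_g`` drawn from the module's
    (loading_mean, loading_sd) and negated for its negative_fraction;
    non-module genes are baseline + eps. Replicate arrays observe the
    condition value plus independent array noise; the emitted matrix is
    linear scale (2^log2). Fixed seed gives byte-identical output.
    """
    spec.validate()
    layout = _layout(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    gene_ids = _gene_ids(spec.n_genes)
    n_g, n_c = spec.n_genes, spec.n_conditions

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n_g)

    # one latent factor per module, plus one shared "SM program" factor
    # joining planted regulators and SM core genes
    n_factors = len(spec.modules) + (1 if spec.n_planted_regulators else 0)
    factors = rng.standard_normal((max(n_factors, 1), n_c))

    loadings = np.zeros(n_g)
    factor_of_gene = np.full(n_g, -1)
    membership: dict[str, int | None] = {g: None for g in gene_ids}
    signs: dict[str, str] = {}
    for m_idx, (mspec, rng_range) in enumerate(zip(spec.modules, layout.module_ranges)):
        idx = np.array(rng_range)
        a = rng.normal(mspec.loading_mean, mspec.loading_sd, idx.size)
        neg = rng.random(idx.size) < mspec.negative_fraction
        a = np.where(neg, -a, a)
        loadings[idx] = a
        factor_of_gene[idx] = m_idx
        for i, ai in zip(idx, a):
            membership[gene_ids[i]] = m_idx
            signs[gene_ids[i]] = "+" if ai >= 0 else "-"

    regulator_ids: list[str] = []
    if spec.n_planted_regulators:
        program = len(spec.modules)
        prog_idx = list(layout.regulator_indices) + [
            layout.core_indices[c] for c in sorted(layout.core_indices)
        ]
        a = rng.normal(spec.regulator_loading_mean, spec.regulator_loading_sd,
                       len(prog_idx))
        n_reg = len(layout.regulator_indices)
        core_neg = rng.random(len(prog_idx) - n_reg) < spec.core_negative_fraction
        a[n_reg:] = np.where(core_neg, -a[n_reg:], a[n_reg:])
        for i, ai in zip(prog_idx, a):
            loadings[i] = ai
            factor_of_gene[i] = program
            membership[gene_ids[i]] = program
            signs[gene_ids[i]] = "+" if ai >= 0 else "-"
        regulator_ids = [gene_ids[i] for i in layout.regulator_indices]

    cond_log2 = baseline[:, None] + rng.normal(0.0, spec.noise_sd, (n_g, n_c))
    in_module = factor_of_gene >= 0
    if in_module.any():
        cond_log2[in_module] += (
            loadings[in_module, None] * factors[factor_of_gene[in_module]]
        )

    reps = spec.replicate_counts()
    condition_ids = [f"cond{c:03d}" for c in range(n_c)]
    array_log2_cols = []
    array_ids: list[str] = []
    array_to_condition: dict[str, str] = {}
    k = 0
    for c, r in enumerate(reps):
        for _ in range(r):
            aid = f"arr{k:04d}"
            array_ids.append(aid)
            array_to_condition[aid] = condition_ids[c]
            array_log2_cols.append(
                cond_log2[:, c] + rng.normal(0.0, spec.array_noise_sd, n_g)
            )
            k += 1
    intensities = pd.DataFrame(
        np.exp2(np.column_stack(array_log2_cols)), index=gene_ids, columns=array_ids
    )

    truth = GroundTruth(
        module_membership=membership,
        loading_signs=signs,
        planted_regulator_ids=regulator_ids,
        term_to_module={},
        sm_cluster_members={
            c: [gene_ids[i] for i in run] for c, run in layout.cluster_ranges.items()
        },
        sm_core_ids=[gene_ids[layout.core_indices[c]]
                     for c in sorted(layout.core_indices)],
        embedded_tf_ids=[gene_ids[i]
                         for i in sorted(layout.embedded_tf_indices.values())],
        baseline_log2={g: float(b) for g, b in zip(gene_ids, baseline)},
    )
    compendium = ExpressionCompendium(
        gene_ids=gene_ids,
        array_ids=array_ids,
        array_to_condition=array_to_condition,
        intensities=intensities,
    )
    return compendium, truth


def generate_catalog(spec: SyntheticSpec, truth: GroundTruth) -> GeneCatalog:
    """Lay genes on synthetic chromosomes and attach functional flags.

    Genes occupy non-overlapping 1-based inclusive intervals in id order over
    eight chromosomes. SM clusters are contiguous coordinate runs with exactly
    one core gene; planted regulators are TF-flagged and sit outside every
    cluster. ``tf_fraction`` background genes are TF-flagged and
    ``informant_fraction`` get a verified-ortholog informant category
    (SM cores are informants of category ``sm_core``).
    """
    spec.validate()
    gene_ids = _gene_ids(spec.n_genes)
    n_chrom = 8
    per_chrom = -(-spec.n_genes // n_chrom)  # ceil
    gene_len, gap = 1500, 500

    cluster_of: dict[str, int] = {}
    cluster_start: set[str] = set()
    for c, members in truth.sm_cluster_members.items():
        for g in members:
            cluster_of[g] = c
        cluster_start.add(members[0])

    # chromosome breaks every ~per_chrom genes, deferred so a cluster run is
    # never split across chromosomes
    chrom_of: list[int] = []
    chrom, count = 1, 0
    for g in gene_ids:
        mid_cluster = g in cluster_of and g not in cluster_start
        if count >= per_chrom and chrom < n_chrom and not mid_cluster:
            chrom += 1
            count = 0
        chrom_of.append(chrom)
        count += 1
    cores = set(truth.sm_core_ids)
    embedded = set(truth.embedded_tf_ids)
    regulators = set(truth.planted_regulator_ids)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    random_tf = rng.random(spec.n_genes) < spec.tf_fraction
    random_informant = rng.random(spec.n_genes) < spec.informant_fraction
    informant_cat = rng.integers(0, len(INFORMANT_CATEGORIES), spec.n_genes)
    hypothetical = rng.random(spec.n_genes) < spec.hypothetical_fraction

    rows = []
    pos_on_chrom = 0
    for i, g in enumerate(gene_ids):
        if i and chrom_of[i] != chrom_of[i - 1]:
            pos_on_chrom = 0
        chrom = f"chr{chrom_of[i]}"
        start = 1 + pos_on_chrom * (gene_len + gap)
        end = start + gene_len - 1
        pos_on_chrom += 1
        in_cluster = g in cluster_of
        is_core = g in cores
        is_tf = g in embedded or g in regulators or (not in_cluster and random_tf[i])
        if is_core:
            category = "sm_core"
        elif random_informant[i] and not in_cluster:
            category = INFORMANT_CATEGORIES[informant_cat[i]]
        else:
            category = "none"
        rows.append(
            {
                "gene_id": g,
                "chromosome": chrom,
                "start": start,
                "end": end,
                "strand": "+" if i % 2 == 0 else "-",
                "is_tf": bool(is_tf),
                "is_hypothetical": bool(hypothetical[i]) and category == "none"
                and not is_tf,
                "informant_category": category,
                "sm_cluster_id": cluster_of.get(g),
                "is_sm_core": is_core,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return GeneCatalog(table=table)


def generate_ontology(
    spec: SyntheticSpec, truth: GroundTruth
) -> tuple[OntologyDAG, AnnotationMap]:
    """Build a rooted is_a DAG and gene annotations concentrated in modules.

    Structure: root -> branch terms -> intermediate terms -> leaf terms
    (depth 3). The first ``n_modules`` leaves are module signature terms: each
    annotates >= 80% of its module's members but only a small fraction of
    background genes, so enrichment of the signature term in a module
    sub-network is guaranteed by construction. Remaining leaf annotations are
    random at ``annotation_rate``. Acyclic by layered construction.
    """
    spec.validate()
    n_modules = len(spec.modules) + (1 if spec.n_planted_regulators else 0)
    n_terms = spec.ontology_terms
    min_terms = 3 + n_modules + 1
    if n_terms < min_terms:
        raise ValueError(f"ontology_terms={n_terms} too small; need >= {min_terms}")

    ids = [f"T:{i + 1:07d}" for i in range(n_terms)]
    root = ids[0]
    n_branch = 2
    n_inter = max(2, (n_terms - 3) // 4)
    branches = ids[1 : 1 + n_branch]
    inters = ids[1 + n_branch : 1 + n_branch + n_inter]
    leaves = ids[1 + n_branch + n_inter :]
    if len(leaves) < n_modules + 1:
        raise ValueError("not enough leaf terms for module signatures")

    names = {root: "biological_process"}
    edges: list[tuple[str, str]] = []
    for i, t in enumerate(branches):
        names[t] = f"branch process {i}"
        edges.append((t, root))
    for i, t in enumerate(inters):
        names[t] = f"intermediate process {i}"
        edges.append((t, branches[i % n_branch]))
    for i, t in enumerate(leaves):
        names[t] = f"leaf process {i}"
        edges.append((t, inters[i % n_inter]))

    dag = build_ontology(
        terms={t: (names[t], "biological_process") for t in ids}, is_a_edges=edges
    )

    gene_ids = _gene_ids(spec.n_genes)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    direct: dict[str, set[str]] = {g: set() for g in gene_ids}
    term_to_module: dict[str, int] = {}
    background_rate = 0.5 * spec.annotation_rate
    for m in range(n_modules):
        sig = leaves[m]
        term_to_module[sig] = m
        members = set(truth.module_genes(m))
        for g in gene_ids:
            p = 0.95 if g in members else background_rate
            if rng.random() < p:
                direct[g].add(sig)
    for t in leaves[n_modules:]:
        hit = rng.random(spec.n_genes) < spec.annotation_rate
        for g, h in zip(gene_ids, hit):
            if h:
                direct[g].add(t)
    truth.term_to_module = term_to_module

    annmap = AnnotationMap(direct={g: frozenset(ts) for g, ts in direct.items()})
    return dag, annmap


def write_artifacts(
    outdir,
    compendium: ExpressionCompendium,
    catalog: GeneCatalog,
    dag: OntologyDAG,
    annmap: AnnotationMap,
) -> dict[str, str]:
    """Emit all synthetic inputs as their standard on-disk formats."""
    from pathlib import Path

    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression_matrix.tsv",
        "condition_map": outdir / "condition_map.tsv",
        "gff3": outdir / "genes.gff3",
        "attributes": outdir / "gene_attributes.tsv",
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
    }
    cio.write_compendium(compendium, paths["matrix"], paths["condition_map"])
    cio.write_catalog(catalog, paths["gff3"], paths["attributes"])
    cio.write_obo(dag, paths["obo"])
    cio.write_gaf(annmap, paths["gaf"])
    return {k: str(v) for k, v in paths.items()}
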
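# Methods

## Model and procedure

The pipeline infers co-expression from a compendium of expression profiles
measured as replicate arrays over cultivation conditions. Stages, in order:

1. **Replicate collapse.** Linear intensities are mapped per array to
   log2(v + c), with pseudocount c = 1 applied only if the matrix contains a
   zero (microarray summarization outputs are positive, so this guards only
   synthetic edge cases). Each condition's profile is the arithmetic mean of
   its arrays' log2 values — the "log2 mean" convention, chosen over
   mean-then-log because averaging on the stabilized scale damps
   multiplicative array noise. Correlations are computed on condition-level
   profiles, not arrays: replicate arrays of one condition are
   pseudo-replicates and would inflate the effective sample size. The engine
   accepts either matrix if the array-level reading is wanted.
2. **All-pairs Spearman.** Rows are rank-transformed once (average ranks for
   ties), centred and L2-normalised, so the full ρ matrix is a blocked
   matrix product; edges are kept at |ρ| ≥ the report threshold. Results are
   independent of block size, and genes with constant profiles are excluded
   (ρ is undefined there — they are reported, not silently given ρ = 0).
3. **Null calibration.** Each gene row is permuted across conditions with
   its own random substream (spawned from one master seed, keyed by row
   index, so results do not depend on iteration order). All-pairs |ρ| on
   this null is compared against a candidate grid (0.3, 0.4, 0.5, 0.6, 0.7);
   the chosen threshold is the smallest candidate no null pair reaches. If
   every candidate is exceeded the result is an explicit *uncalibrated*
   status, never a silent default. One full permuted replicate of the whole
   matrix is used (replicates configurable); at compendium scale the null
   already contains ~10⁸ pairs, so the tail is well resolved.
4. **Sub-networks.** Per query gene, partners at |ρ| ≥ 0.5 ("stringent") and
   ≥ 0.7 ("highly stringent"), split into positive and negative lists —
   anticorrelation is biological signal (repression, antagonistic programs),
   not noise. Informant-prioritized overlays intersect a sub-network with
   the informant set (genes with wet-lab validation or predicted SM core
   enzymes); this is a filter on the partner list, not a requirement that
   *only* informants be partners.
5. **GO enrichment.** Direct annotations are closed under is_a ancestors
   (true-path rule) before counting; the one-sided upper-tail hypergeometric
   p (= Fisher exact, enrichment direction only) is computed per term with
   K ≥ 1 against the whole-genome background, including unannotated genes.
   Default decision rule is uncorrected p < 0.05; Bonferroni over the tested
   terms is available. Study sets can be combined, positive-only, or
   negative-only partners — all three modes are exposed because sign
   conventions differ between studies.
6. **Landscape.** Per-gene mean of condition-level log2 values, ordered by
   chromosome and start coordinate, classed low/medium/high by genome-wide
   quantiles (terciles by default). Quantiles are a reproducible surrogate
   for what is otherwise a visual judgement; boundary ties fall to the lower
   class so the "high" tier is conservative.
7. **SM clusters and regulators.** A core gene is "expressed" if its
   condition-level value exceeds a floor in ≥ 1 condition; the floor
   defaults to the 20th percentile of all gene×condition values — a
   platform-free, monotone-invariant stand-in for a detection call. Cluster
   coherence is the fraction of non-core members co-expressed with a core
   (max over cores when several exist); embedded-TF co-expression is flagged
   the same way. The trans-regulator scan scores every TF/chromatin-
   regulator gene *outside* all clusters by how many core genes it reaches
   at the cutoff (positively and negatively counted separately), keeps
   candidates reaching ≥ `min_cores` (default 2) and ranks by total core
   count with ties broken by gene id, so ranking is independent of catalog
   row order. A connected-component view of the core-incident network is
   provided as a convenience for exploring the global SM program; it is a
   view, not a calibrated statistic.

## Synthetic data: what it emulates, what it does not

The generator draws, per co-expression module, one latent factor per
condition (standard normal); a member gene's condition-level log2 value is
`baseline_g + a_g·f_mc + ε` with loading a_g ~ N(loading_mean, loading_sd),
negated for a configurable fraction of members (mixed-sign modules), and
ε ~ N(0, noise_sd). Non-module genes are baseline + ε. Replicate arrays
observe the condition value plus N(0, 0.1) array noise; the emitted matrix
is 2^log2. Since Spearman is invariant to the monotone 2^x map, correlation
targets set on the log2 scale hold on the emitted linear matrix exactly.

Default geometry is 155 conditions observed by 283 arrays (128 duplicated
conditions + 27 singletons), the compendium scale this pipeline is designed
for. Defaults elsewhere: baseline log2 mean 6, sd 1.5 (a plausible
log-intensity spread); noise_sd 0.5; module loading 1.5 — giving planted
within-module correlations around 0.8–0.9, strong but not degenerate, so
that dual-stringency behaviour is exercised.

Catalogs place genes in id order on eight chromosomes (non-overlapping
1-based intervals); SM clusters are contiguous runs with exactly one core
(first gene) and, in a configurable fraction of clusters, one embedded TF
(second gene). Planted trans-regulators are TF-flagged genes outside all
clusters that share a dedicated latent factor with every core gene —
emulating a global regulator of secondary metabolism; a fraction of cores
may load negatively so the scan sees mixed-sign patterns. Two placement
modes are mutually exclusive by design: clusters aligned on coherent modules
(for coherence ground truth) versus cores loaded on a regulator program
(each gene loads on at most one factor).

The ontology is a four-layer rooted is_a DAG (root → branches →
intermediates → leaves). One leaf per module is a "signature" term
annotating ~95% of its module's members and half the background
`annotation_rate` elsewhere, guaranteeing detectable enrichment of the
signature term in module sub-networks; remaining leaves annotate genes at
`annotation_rate` (default 0.05).

Not emulated: probe-level microarray effects, present/absent detection
calls, batch effects, correlated (non-factor) noise, condition-dependent
cluster silencing dynamics. Passing tests therefore demonstrate that the
machinery recovers structure of this factor-model form at these
signal-to-noise ratios — not that real compendia contain such structure, nor
anything about normalization quality upstream of the input matrix.

## Numerical choices and edge cases

- Threshold comparisons use ≥ throughout (a pair at exactly 0.5 is kept).
- ρ is clipped to [−1, 1] after the normalized dot product; the
  hand-checkable five-point example evaluates to 0.8 exactly because the
  denominator is computed as √(v_x·v_y).
- Engine-vs-oracle agreement (blocked product vs per-pair rank-then-Pearson)
  is held to 1e−10; enrichment p-values are held to 1e−10 against an exact
  rational (Fraction-arithmetic) hypergeometric tail.
- Constant-profile genes: excluded from pairing, error on direct query.
- Fewer than 3 conditions: hard error (rank geometry is degenerate; with 3
  columns every null ρ lies in {±1, ±1/2} and calibration correctly reports
  uncalibrated).
- Degenerate all-equal landscape: all loci classed medium, with a warning.
- Edge lists are canonicalized (gene_a < gene_b by id, then sorted), so
  outputs are byte-stable across reruns and block sizes.

## Problem sizes used in validation

Unit and property tests run on 200–600-gene designs (seconds). The
full-scale checks use a 1000-gene × 155-condition compendium for module
recovery and the pipeline run, and a 14,489-gene structureless compendium
(~1.05 × 10⁸ pairs) for null calibration — the scale at which the null tail
crosses |0.4| but not |0.5|, so the calibrated threshold lands at 0.5. These
sizes were chosen as the smallest designs that exercise every code path at
compendium-realistic pair counts.

## Known limitations

- The permutation null preserves marginals but not inter-condition
  covariance of technical origin; on real data, batch structure could
  inflate the null tail relative to this model.
- Sub-network GO enrichment treats partner sets as simple gene lists;
  no weighting by |ρ| and no multiple-testing control across queries
  (per-query Bonferroni only).
- The "expressed" floor (20th percentile) is a pragmatic surrogate for
  platform detection calls and should be recalibrated for non-microarray
  inputs.
- Cluster coherence uses the max over core genes, which is permissive for
  multi-core clusters.
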
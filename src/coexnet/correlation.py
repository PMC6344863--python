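"""All-pairs Spearman correlation with permutation-null threshold calibration.

The co-expression network is built from Spearman's rank correlation
coefficient (rho) between every unordered pair of gene expression profiles.
Because raw correlation magnitudes carry no intrinsic significance scale, the
reporting threshold is calibrated against a permutation null: each gene's
profile is shuffled independently across columns, destroying all inter-gene
structure while preserving every marginal distribution exactly, and the
smallest candidate cutoff that no permuted pair exceeds is adopted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_CANDIDATES = (0.3, 0.4, 0.5, 0.6, 0.7)


class ConstantProfileError(ValueError):
    """Spearman correlation is undefined for a constant profile (no rank variation)."""


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-tie ranks.

    Raises ``ConstantProfileError`` (never returns 0) when either vector is
    constant, since ranks then have zero variance and rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    vx = sx @ sx
    vy = sy @ sy
    if vx == 0.0 or vy == 0.0:
        raise ConstantProfileError("constant profile: Spearman rho undefined")
    rho = float((sx @ sy) / np.sqrt(vx * vy))
    return min(1.0, max(-1.0, rho))


@dataclass
class CorrelationResult:
    """Sparse thresholded edge set of an all-pairs Spearman computation.

    Edges are canonically ordered (``gene_a < gene_b`` by id) and stored only
    at ``|rho| >= report_threshold``. ``valid_genes`` excludes constant
    profiles, for which rho is undefined.
    """

    gene_ids: list[str]
    report_threshold: float
    valid_genes: set[str]
    edges: pd.DataFrame  # columns: gene_a, gene_b, rho
    _adjacency: dict[str, list[tuple[str, float]]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_pairs_total(self) -> int:
        v = len(self.valid_genes)
        return v * (v - 1) // 2

    def n_pairs_signed(self, cutoff: float | None = None) -> tuple[int, int]:
        """(positive, negative) edge counts at ``|rho| >= cutoff``."""
        cutoff = self.report_threshold if cutoff is None else cutoff
        if cutoff < self.report_threshold:
            raise ValueError(
                f"cutoff {cutoff} below report_threshold {self.report_threshold}: "
                "edges below the report threshold were not stored"
            )
        rho = self.edges["rho"].to_numpy()
        keep = np.abs(rho) >= cutoff
        return int(np.sum(keep & (rho > 0))), int(np.sum(keep & (rho < 0)))

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        """gene -> [(partner, rho), ...] over stored edges; built once, cached."""
        if self._adjacency is None:
            adj: dict[str, list[tuple[str, float]]] = {g: [] for g in self.gene_ids}
            for a, b, r in self.edges.itertuples(index=False):
                adj[a].append((b, r))
                adj[b].append((a, r))
            self._adjacency = adj
        return self._adjacency

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# report_threshold={self.report_threshold}\n")
            fh.write("gene_a\tgene_b\trho\n")
            for a, b, r in self.edges.itertuples(index=False):
                fh.write(f"{a}\t{b}\t{r:.6f}\n")


@dataclass
class NullCalibration:
    """Outcome of permutation-null threshold calibration.

    ``chosen_threshold`` is the smallest candidate cutoff that zero permuted
    pairs reach; ``None`` means no candidate qualified and the caller must
    decide (an explicit "uncalibrated" status, never a silent default).
    """

    candidate_thresholds: tuple[float, ...]
    exceedance_counts: dict[float, int]
    max_abs_rho_null: float
    chosen_threshold: float | None
    n_null_pairs: int
    seed: int

    @property
    def calibrated(self) -> bool:
        return self.chosen_threshold is not None

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# seed={self.seed} n_pairs={self.n_null_pairs} "
                f"max_abs_rho_null={self.max_abs_rho_null:.6f} "
                f"chosen_threshold={self.chosen_threshold}\n"
            )
            fh.write("candidate\texceedance_count\n")
            for c in self.candidate_thresholds:
                fh.write(f"{c}\t{self.exceedance_counts[c]}\n")


def _rank_rows(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average-tie ranks per row, centred and L2-normalised; flags valid rows.

    Returns (Z, valid) where Z[i] @ Z[j] is exactly the Spearman rho of rows
    i, j whenever both are valid; constant rows yield a zero vector.
    """
    values = matrix.to_numpy(dtype=float)
    ranks = rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    return ranks / safe[:, None], valid


def all_pairs(
    matrix: pd.DataFrame,
    report_threshold: float = 0.5,
    block_size: int = 512,
) -> CorrelationResult:
    """Evaluate Spearman rho for every unordered gene pair; keep significant edges.

    ``matrix`` is gene x condition (rows indexed by gene id). Computation is
    blocked over rows so working memory stays bounded; the edge set is
    independent of ``block_size``. Genes with constant profiles are excluded
    from pairing and reported via ``valid_genes``.
    """
    if matrix.shape[1] < 3:
        raise ValueError(f"need >= 3 conditions, got {matrix.shape[1]}")
    if not (0.0 < report_threshold <= 1.0):
        raise ValueError("report_threshold must be in (0, 1]")
    gene_ids = [str(g) for g in matrix.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in matrix")

    Z, valid = _rank_rows(matrix)
    n = Z.shape[0]
    rows_a: list[np.ndarray] = []
    rows_b: list[np.ndarray] = []
    rhos: list[np.ndarray] = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = Z[start:stop] @ Z.T  # (stop-start, n)
        # strict upper triangle in global row order, valid pairs only
        gi = np.arange(start, stop)[:, None]
        gj = np.arange(n)[None, :]
        mask = (gj > gi) & valid[start:stop][:, None] & valid[None, :]
        mask &= np.abs(block) >= report_threshold
        ii, jj = np.nonzero(mask)
        rows_a.append(ii + start)
        rows_b.append(jj)
        rhos.append(np.clip(block[ii, jj], -1.0, 1.0))

    ia = np.concatenate(rows_a) if rows_a else np.empty(0, dtype=int)
    ib = np.concatenate(rows_b) if rows_b else np.empty(0, dtype=int)
    rho = np.concatenate(rhos) if rhos else np.empty(0, dtype=float)

    ids = np.asarray(gene_ids, dtype=object)
    a = ids[ia]
    b = ids[ib]
    # canonical gene_a < gene_b in id order
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap]
    order = np.lexsort((b, a))
    edges = pd.DataFrame({"gene_a": a[order], "gene_b": b[order], "rho": rho[order]})

    valid_genes = {g for g, ok in zip(gene_ids, valid) if ok}
    if not valid_genes:
        import warnings

        warnings.warn("all gene profiles are constant: empty correlation result")
    return CorrelationResult(
        gene_ids=gene_ids,
        report_threshold=report_threshold,
        valid_genes=valid_genes,
        edges=edges,
    )


def permute_matrix(matrix: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Shuffle each gene row independently across columns.

    Each row gets its own random stream spawned from the master seed and keyed
    by row index, so the result is independent of iteration order. Marginal
    distributions are preserved exactly.
    """
    values = matrix.to_numpy(dtype=float).copy()
    streams = np.random.SeedSequence(seed).spawn(values.shape[0])
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        values[i] = values[i, rng.permutation(values.shape[1])]
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def calibrate_threshold(
    matrix: pd.DataFrame,
    candidates: Iterable[float] = DEFAULT_CANDIDATES,
    seed: int = 0,
    block_size: int = 512,
) -> NullCalibration:
    """Calibrate the co-expression cutoff on one fully permuted replicate.

    All-pairs |rho| is computed on the row-permuted matrix and, per candidate
    cutoff, the number of null pairs reaching it is counted. The chosen
    threshold is the smallest candidate with zero exceedances.
    """
    candidates = tuple(sorted(float(c) for c in candidates))
    if not candidates:
        raise ValueError("no candidate thresholds supplied")
    if matrix.shape[1] < 3:
        raise ValueError(f"need >= 3 conditions, got {matrix.shape[1]}")

    permuted = permute_matrix(matrix, seed)
    Z, valid = _rank_rows(permuted)
    n = Z.shape[0]
    counts = {c: 0 for c in candidates}
    max_abs = 0.0
    n_pairs = 0
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = np.abs(Z[start:stop] @ Z.T)
        gi = np.arange(start, stop)[:, None]
        gj = np.arange(n)[None, :]
        mask = (gj > gi) & valid[start:stop][:, None] & valid[None, :]
        vals = block[mask]
        n_pairs += vals.size
        if vals.size:
            max_abs = max(max_abs, float(vals.max()))
            for c in candidates:
                counts[c] += int(np.count_nonzero(vals >= c))

    chosen = next((c for c in candidates if counts[c] == 0), None)
    return NullCalibration(
        candidate_thresholds=candidates,
        exceedance_counts=counts,
        max_abs_rho_null=max_abs,
        chosen_threshold=chosen,
        n_null_pairs=n_pairs,
        seed=seed,
    )
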
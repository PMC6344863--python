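"""Chromosomal expression landscape: per-gene mean log2 expression across all
conditions, ordered along each chromosome, with low/medium/high locus classes.

A practical use case is choosing genomic integration loci by expression level;
classes are assigned genome-wide by quantile (terciles by default — the
thresholds are a reproducible surrogate for what is otherwise a visual call).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import ExpressionCompendium, GeneCatalog

logger = logging.getLogger(__name__)


def chromosomal_landscape(
    compendium: ExpressionCompendium, catalog: GeneCatalog
) -> pd.DataFrame:
    """Mean condition-level log2 expression per gene, in chromosomal order.

    Returns a DataFrame with columns gene_id, chromosome, start, mean_log2,
    sorted by (chromosome, start). Genes missing from either input are logged
    and excluded; an empty intersection is an error.
    """
    if compendium.condition_log2 is None:
        raise ValueError("condition_log2 not filled; run collapse_conditions first")
    common = [g for g in catalog.gene_ids if g in compendium.condition_log2.index]
    if not common:
        raise ValueError("no genes shared between catalog and compendium")
    n_missing = len(catalog.gene_ids) - len(common)
    if n_missing:
        logger.info("%d catalog genes absent from compendium, excluded", n_missing)
    mean_log2 = compendium.condition_log2.loc[common].mean(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": common,
            "chromosome": catalog.table.loc[common, "chromosome"].to_numpy(),
            "start": catalog.table.loc[common, "start"].to_numpy(),
            "mean_log2": mean_log2.to_numpy(),
        }
    )
    return out.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)


def classify_loci(
    profile: pd.DataFrame, quantiles: tuple[float, float] = (1 / 3, 2 / 3)
) -> pd.DataFrame:
    """Attach low/medium/high expression classes by genome-wide quantile.

    Genes strictly below the lower quantile of mean_log2 are ``low``, strictly
    above the upper are ``high``, the rest ``medium`` — so a tie at a boundary
    falls to the lower class. A degenerate (all-equal) distribution yields all
    ``medium`` with a warning. Thresholds are recorded in ``profile.attrs``.
    """
    lo_q, hi_q = quantiles
    if not (0.0 < lo_q <= hi_q < 1.0):
        raise ValueError(f"invalid quantiles {quantiles}")
    values = profile["mean_log2"].to_numpy()
    lo, hi = np.quantile(values, [lo_q, hi_q])
    out = profile.copy()
    if lo == hi and values.min() == values.max():
        warnings.warn("degenerate expression distribution: all loci classed medium")
        out["expression_class"] = "medium"
    else:
        cls = np.full(len(values), "medium", dtype=object)
        cls[values < lo] = "low"
        cls[values > hi] = "high"
        out["expression_class"] = cls
    out.attrs["thresholds"] = (float(lo), float(hi))
    out.attrs["quantiles"] = (float(lo_q), float(hi_q))
    return out


def write_landscape(profile: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        lo, hi = profile.attrs.get("thresholds", (float("nan"), float("nan")))
        fh.write(f"# coexnet landscape; class thresholds low<{lo:.6g} high>{hi:.6g}\n")
        profile.to_csv(fh, sep="\t", index=False)
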
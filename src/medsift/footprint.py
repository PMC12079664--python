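"""Signaling-footprint statistics against pathway-defining knockouts.

A pathway footprint is a set of target genes (50 by convention) whose
coordinated expression change marks perturbation of that signaling system,
together with the expression delta of the knockout that defines it.  For a
query mutant, two statistics are computed over the footprint genes:

- pathway activity a_P = sum of query deltas / sum of defining deltas
  (1 for the defining knockout itself);
- the Spearman correlation between query and defining deltas.

Deltas are differences of mean log2 expression (mutant - wild type) after
24 h of differentiation; wild-type conditions of each batch serve as the
batch correction baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PathwayFootprint:
    """A pathway's target-gene set and defining-knockout delta vector."""

    name: str
    delta_def: pd.Series  # indexed by gene; one entry per footprint gene

    @property
    def genes(self) -> list[str]:
        return list(self.delta_def.index)


def query_delta(
    wild_type: pd.DataFrame,
    mutant: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.Series:
    """Per-gene mean log2 expression difference, mutant - wild type.

    Inputs are linear-scale gene x replicate matrices for the matched
    condition (24 h of differentiation).  Single-replicate inputs are
    allowed with a warning.
    """
    if wild_type.shape[1] == 0 or mutant.shape[1] == 0:
        raise ValueError("both genotypes need at least one sample at the timepoint")
    if wild_type.shape[1] == 1 or mutant.shape[1] == 1:
        logger.warning("single-replicate input to query_delta; delta has no averaging")
    if genes is not None:
        wild_type = wild_type.loc[genes]
        mutant = mutant.loc[genes]
    return np.log2(mutant).mean(axis=1) - np.log2(wild_type).mean(axis=1)


def pathway_activity(delta_query: pd.Series, fp: PathwayFootprint) -> float:
    """Activity a_P = sum of query deltas over footprint genes / sum of
    defining deltas."""
    denom = float(fp.delta_def.sum())
    if denom == 0:
        raise ValueError(f"degenerate footprint {fp.name}: defining deltas sum to zero")
    num = float(delta_query.reindex(fp.genes).sum())
    return num / denom


def footprint_correlation(delta_query: pd.Series, fp: PathwayFootprint) -> float:
    """Spearman correlation of query vs defining deltas over footprint genes.

    Ties receive average ranks.  A constant vector makes the correlation
    undefined; NaN is returned and should be reported as missing.
    """
    q = delta_query.reindex(fp.genes).to_numpy(dtype=float)
    d = fp.delta_def.to_numpy(dtype=float)
    if np.sum(~np.isnan(q)) < 3:
        raise ValueError("need >= 3 genes with defined values")
    if np.nanstd(q) == 0 or np.nanstd(d) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(q, d, nan_policy="omit")
    return float(rho)


def footprint_panel(
    query_deltas: dict[str, pd.Series],
    footprints: list[PathwayFootprint],
    batch_wt_delta: dict[str, pd.Series] | None = None,
    query_batches: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Activity and correlation for every query x pathway tile.

    Each query's delta is batch-corrected by subtracting its batch's
    wild-type delta before scoring (``query_batches`` maps query -> batch;
    omitted queries or a missing ``batch_wt_delta`` mean no correction).
    Pathways whose genes are absent from a query's universe yield a missing
    tile, logged rather than raised.
    """
    rows = []
    for qname, delta in query_deltas.items():
        corrected = delta
        if batch_wt_delta and query_batches and qname in query_batches:
            wt = batch_wt_delta[query_batches[qname]]
            corrected = delta - wt.reindex(delta.index).fillna(0.0)
        for fp in footprints:
            missing = [g for g in fp.genes if g not in corrected.index]
            if missing:
                logger.warning(
                    "query %s: pathway %s missing %d genes; tile skipped",
                    qname, fp.name, len(missing),
                )
                continue
            rows.append(
                {
                    "query": qname,
                    "pathway": fp.name,
                    "activity": pathway_activity(corrected, fp),
                    "spearman": footprint_correlation(corrected, fp),
                }
            )
    return pd.DataFrame(rows, columns=["query", "pathway", "activity", "spearman"])
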
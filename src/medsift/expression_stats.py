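"""Differential-expression contract, target sets, and single-cell QC rules.

The DE stand-in works on log2(x+1)-transformed expression with an
unequal-variance (Welch) two-sample test and Benjamini-Hochberg adjustment;
downstream statistics consume only (log2fc, padj).  Single-cell QC follows
strict removal phrasing: barcodes with <= ``min_genes`` detected genes or
mitochondrial fraction >= ``max_mito`` are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    """Signed target set split by direction of regulation."""

    up: list[str]
    down: list[str]

    @property
    def all(self) -> list[str]:
        return self.up + self.down


def simple_de(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Two-group differential expression on log2(x + 1).

    log2fc is the mean log2(x+1) difference (b - a); p comes from Welch's
    t-test per gene; padj is Benjamini-Hochberg over all tested genes.
    Requires >= 2 replicates per group.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = np.log2(matrix[group_a].to_numpy(dtype=float) + 1.0)
    b = np.log2(matrix[group_b].to_numpy(dtype=float) + 1.0)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": lfc, "p": p, "padj": padj}, index=matrix.index)


def define_target_set(
    fc: pd.DataFrame,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> GeneSet:
    """Signed target set: |log2fc| > lfc_min and padj < padj_max.

    Defaults are the FGF-target thresholds (fold change above 2x and
    adjusted P below 0.05).
    """
    if lfc_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    sig = fc[(fc["log2fc"].abs() > lfc_min) & (fc["padj"] < padj_max)]
    return GeneSet(
        up=list(sig.index[sig["log2fc"] > 0]),
        down=list(sig.index[sig["log2fc"] < 0]),
    )


@dataclass
class SCCountMatrix:
    """Gene x cell integer counts with mitochondrial gene annotation."""

    counts: pd.DataFrame
    mito_genes: list[str] = field(default_factory=list)

    @property
    def detected_genes(self) -> pd.Series:
        """Number of nonzero genes per cell."""
        return (self.counts > 0).sum(axis=0)

    @property
    def mito_fraction(self) -> pd.Series:
        """Fraction of counts from mitochondrial genes, per cell."""
        total = self.counts.sum(axis=0)
        mito = self.counts.loc[self.counts.index.isin(self.mito_genes)].sum(axis=0)
        return mito / total.replace(0, np.nan)


def sc_qc_filter(
    sc: SCCountMatrix,
    min_genes: int = 2500,
    max_mito: float = 0.15,
) -> SCCountMatrix:
    """Remove barcodes with <= min_genes detected genes or >= max_mito mito.

    Retained cells satisfy detected > min_genes AND mito fraction < max_mito
    (both boundaries removed, matching the removal phrasing).
    """
    keep = (sc.detected_genes > min_genes) & (sc.mito_fraction.fillna(1.0) < max_mito)
    if not keep.any():
        warnings.warn("QC filter removed every cell", stacklevel=2)
    return SCCountMatrix(counts=sc.counts.loc[:, keep], mito_genes=sc.mito_genes)


def sc_normalize(sc: SCCountMatrix, scale: float = 10_000.0) -> pd.DataFrame:
    """Depth-normalize to ``scale`` counts per cell, then log1p.

    value = log1p(count / cell_total * scale).  A zero-total cell is an
    error naming the barcode.
    """
    totals = sc.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total cell(s): {list(zero.index)}")
    return np.log1p(sc.counts / totals * scale)


def sc_marker_test(
    normalized: pd.DataFrame,
    groups: dict[str, list[str]],
    min_diff: float = 0.5,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Rank-sum marker test restricted to genes with a minimum mean
    log1p-expression difference between the two groups.

    Genes whose absolute group-mean difference is below ``min_diff`` are not
    tested; BH adjustment runs over exactly the tested genes.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name_a, cells_a), (name_b, cells_b) = groups.items()
    if len(cells_a) < min_cells or len(cells_b) < min_cells:
        raise ValueError(f"each group needs >= {min_cells} cells")
    a = normalized[cells_a]
    b = normalized[cells_b]
    diff = b.mean(axis=1) - a.mean(axis=1)
    tested = diff.index[diff.abs() >= min_diff]
    if len(tested) == 0:
        return pd.DataFrame(columns=["mean_diff", "p", "padj"])
    p = np.array(
        [
            stats.ranksums(b.loc[g].to_numpy(), a.loc[g].to_numpy()).pvalue
            for g in tested
        ]
    )
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"mean_diff": diff[tested], "p": p, "padj": padj}, index=tested
    ).sort_values("padj")
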
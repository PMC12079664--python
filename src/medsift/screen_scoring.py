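"""Guide- and gene-level scoring of sorted-population CRISPR screen counts.

The pipeline is: total-count normalization -> per-guide log2 fold change of a
sorted gate against the unsorted reference -> percentile ranks over the full
library (controls included) -> alpha-RRA gene scores -> permutation p-values
with Benjamini-Hochberg FDR -> compound hit selection across conditions.

The alpha-RRA score of a gene with guide percentiles u_(1) <= ... <= u_(n)
is rho = min_k P(Beta(k, n-k+1) <= u_(k)) over guides with u <= alpha: the
probability that the k-th order statistic of n uniforms falls below the
observed k-th percentile.  Small rho means the gene's guides sit improbably
high in the enrichment ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.25


def total_count_normalize(counts: pd.DataFrame, sample_cols: list[str]) -> pd.DataFrame:
    """Rescale each sample column so its total equals the mean original total.

    Non-sample columns (gene map, flags) pass through unchanged.
    """
    totals = counts[sample_cols].sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    target = float(totals.mean())
    out = counts.copy()
    for c in sample_cols:
        out[c] = counts[c] * (target / totals[c])
    return out


def guide_log2fc(
    counts: pd.DataFrame,
    sorted_col: str,
    reference_col: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide enrichment of a sorted gate over the unsorted reference.

    log2fc = log2((sorted + pc) / (reference + pc)).  Ranks are assigned by
    descending log2fc with ties broken by row order (stable); the percentile
    of rank k among N guides is k/N, so the most-enriched guide has
    percentile 1/N.
    """
    for col in (sorted_col, reference_col):
        if col not in counts.columns:
            raise ValueError(f"column {col!r} not in table")
    lfc = np.log2((counts[sorted_col] + pseudocount) / (counts[reference_col] + pseudocount))
    order = np.argsort(-lfc.to_numpy(), kind="stable")
    rank = np.empty(len(lfc), dtype=int)
    rank[order] = np.arange(1, len(lfc) + 1)
    out = pd.DataFrame(
        {
            "gene": counts["gene"],
            "is_control": counts.get("is_control", False),
            "log2fc": lfc,
            "rank": rank,
            "percentile": rank / len(lfc),
        },
        index=counts.index,
    )
    return out


def _rra_rho(u: np.ndarray, n: int, alpha: float) -> float:
    """alpha-RRA rho for sorted percentiles u (ascending) of an n-guide gene."""
    u = np.sort(np.asarray(u, dtype=float))
    k = np.arange(1, n + 1)
    participating = u <= alpha
    if not participating.any():
        return 1.0
    beta_k = stats.beta.cdf(u[participating], k[participating], n - k[participating] + 1)
    return float(beta_k.min())


def alpha_rra_score(
    stats_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    gene_col: str = "gene",
    exclude_controls: bool = True,
) -> pd.Series:
    """Per-gene alpha-RRA score from a guide stats table with percentiles.

    Percentiles must have been computed over the full library (controls
    included); control guides are excluded from gene grouping unless
    ``exclude_controls`` is False.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    tbl = stats_table
    if exclude_controls and "is_control" in tbl.columns:
        tbl = tbl[~tbl["is_control"].astype(bool)]
    rho = tbl.groupby(gene_col, sort=True)["percentile"].apply(
        lambda u: _rra_rho(u.to_numpy(), len(u), alpha)
    )
    rho.name = "rho"
    return rho


def permutation_fdr(
    rho: pd.Series,
    stats_table: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    gene_col: str = "gene",
) -> pd.DataFrame:
    """Permutation p-values and BH FDR for per-gene rho scores.

    Null rho values are generated by drawing n guide percentiles without
    replacement from the observed percentile pool (the full library,
    controls included) and rescoring; p = (1 + #{rho_null <= rho_obs}) /
    (1 + n_perm).  Deterministic under ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (tail estimate unstable below)")
    rng = np.random.default_rng(seed)
    pool = stats_table["percentile"].to_numpy()

    tbl = stats_table
    if "is_control" in tbl.columns:
        tbl = tbl[~tbl["is_control"].astype(bool)]
    n_guides = tbl.groupby(gene_col)["percentile"].size()

    # one null distribution per distinct guide count
    null_by_n: dict[int, np.ndarray] = {}
    for n in sorted(n_guides.unique()):
        draws = np.empty(n_perm)
        for i in range(n_perm):
            u = rng.choice(pool, size=n, replace=False)
            draws[i] = _rra_rho(u, n, alpha)
        null_by_n[n] = np.sort(draws)

    genes = rho.index
    p = np.empty(len(genes))
    for i, g in enumerate(genes):
        n = int(n_guides[g])
        null = null_by_n[n]
        p[i] = (1 + np.searchsorted(null, rho[g], side="right")) / (1 + n_perm)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"rho": rho, "p_perm": p, "fdr": fdr, "n_guides": n_guides.reindex(genes)},
        index=genes,
    )


def gene_lfc_alphamean(
    stats_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    gene_col: str = "gene",
) -> pd.Series:
    """Gene-level log2 fold change: mean over guides with percentile <= alpha.

    Genes with no guide passing the alpha cut fall back to the mean over all
    of their guides.
    """
    tbl = stats_table
    if "is_control" in tbl.columns:
        tbl = tbl[~tbl["is_control"].astype(bool)]

    def agg(group: pd.DataFrame) -> float:
        passing = group[group["percentile"] <= alpha]
        use = passing if len(passing) else group
        return float(use["log2fc"].mean())

    out = tbl.groupby(gene_col, sort=True)[["percentile", "log2fc"]].apply(agg)
    out.name = "lfc_alphamean"
    return out


def score_condition(
    counts: pd.DataFrame,
    gate_col: str,
    reference_col: str = "unsorted",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full gene-level scoring of one sorted condition.

    Normalizes the two columns, computes guide log2 fold changes and
    percentiles over the full library, then alpha-RRA rho, permutation p,
    BH FDR and the alphamean gene LFC.
    """
    norm = total_count_normalize(counts, [gate_col, reference_col])
    gstats = guide_log2fc(norm, gate_col, reference_col, pseudocount=pseudocount)
    rho = alpha_rra_score(gstats, alpha=alpha)
    table = permutation_fdr(rho, gstats, n_perm=n_perm, alpha=alpha, seed=seed)
    table["lfc_alphamean"] = gene_lfc_alphamean(gstats, alpha=alpha)
    return table


def select_hits(
    fdr_tables: dict[str, pd.Series],
    primary: float = 0.05,
    secondary: float = 0.2,
    min_secondary: int = 2,
) -> pd.DataFrame:
    """Compound hit rule across conditions.

    A gene is a hit iff its FDR is <= ``primary`` in at least one condition,
    or <= ``secondary`` in at least ``min_secondary`` conditions.  Genes
    missing from a condition count as FDR 1 there (conservative).
    """
    if not fdr_tables:
        raise ValueError("need at least one condition FDR table")
    universe = sorted(set().union(*(set(t.index) for t in fdr_tables.values())))
    out = pd.DataFrame(index=pd.Index(universe, name="gene"))
    for cond, t in fdr_tables.items():
        out[cond] = t.reindex(universe).fillna(1.0)
    fdr = out.to_numpy()
    out["is_hit"] = (fdr.min(axis=1) <= primary) | ((fdr <= secondary).sum(axis=1) >= min_secondary)
    return out


def control_enrichment_summary(stats_table: pd.DataFrame) -> dict:
    """Compare enrichment of gene-targeting vs non-targeting control guides.

    Returns class-wise mean log2fc, empirical CDF callables, and a
    two-sample rank-sum z statistic with its normal-approximation p-value
    (targeting > control is positive z).
    """
    is_ctrl = stats_table["is_control"].astype(bool)
    targeting = stats_table.loc[~is_ctrl, "log2fc"].to_numpy()
    control = stats_table.loc[is_ctrl, "log2fc"].to_numpy()
    if targeting.size == 0 or control.size == 0:
        raise ValueError("both targeting and control classes must be non-empty")
    z, p = stats.ranksums(targeting, control)

    def ecdf(x: np.ndarray):
        xs = np.sort(x)

        def f(v):
            return np.searchsorted(xs, v, side="right") / xs.size

        return f

    return {
        "mean_log2fc_targeting": float(targeting.mean()),
        "mean_log2fc_control": float(control.mean()),
        "ecdf_targeting": ecdf(targeting),
        "ecdf_control": ecdf(control),
        "ranksum_z": float(z),
        "ranksum_p": float(p),
    }
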
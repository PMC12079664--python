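"""Differentiation-transition dynamics: delay, slopes, and ratio modes.

Three estimators characterize how a mutant's transcriptional response to
differentiation differs from the wild type's:

- **Differentiation delay**: the signed time offset at which the mutant's
  naive-marker expression change best matches a reference differentiation
  time course (normalized Euclidean distance minimized over a fine time
  grid).
- **Slopes of regulation**: per-gene ratio of the mutant's log2 expression
  change over differentiation to the wild type's, on marker panels or the
  100 genes with the strongest down-/up-regulation; a globally attenuated
  response gives slopes below one.
- **Fold-change-ratio mode**: the mode of the linear-scale ratio of mutant
  to wild-type fold changes over a signed target set, located as the argmax
  of a Gaussian kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import GeneSet

#: Naive pluripotency marker panel used for delay estimation.
NAIVE_MARKERS = ("Prdm14", "Tfcp2l1", "Klf4", "Tbx3", "Nanog", "Zfp42", "Esrrb")

SLOPE_EPSILON = 0.1  # log2 units; genes with |wild-type change| below are excluded


@dataclass
class DelayEstimate:
    """Distance curve over the search grid and its minimizer.

    ``delta_h`` = t* - nominal duration (signed hours; negative means the
    sample looks less far along than the nominal time).  ``curve`` holds the
    min-max rescaled distance for plotting; the estimation uses the raw
    distance, whose minimum is at the same t*.
    """

    t_star: float
    delta_h: float
    curve: pd.DataFrame  # columns: time_h, distance (rescaled to [0, 1])
    d_min: float
    markers_used: list[str]


def marker_change(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    cond_from: str,
    cond_to: str,
    markers: tuple[str, ...] = NAIVE_MARKERS,
) -> pd.Series:
    """Per-marker mean log2 expression difference, cond_to - cond_from.

    ``matrix`` is linear-scale genes x samples; ``metadata`` maps sample ->
    condition (column 'condition').
    """
    missing = [m for m in markers if m not in matrix.index]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    for cond in (cond_from, cond_to):
        if not (metadata["condition"] == cond).any():
            raise ValueError(f"condition {cond!r} absent from metadata")
    cols_from = metadata.index[metadata["condition"] == cond_from]
    cols_to = metadata.index[metadata["condition"] == cond_to]
    log2 = np.log2(matrix.loc[list(markers)])
    return log2[cols_to].mean(axis=1) - log2[cols_from].mean(axis=1)


def estimate_delay(
    change_vector: pd.Series,
    reference: pd.DataFrame,
    grid_step_h: float = 0.1,
    nominal_h: float = 24.0,
) -> DelayEstimate:
    """Locate the reference time whose change vector best matches the query.

    Reference change-to-time-t vectors are reference(t) - reference(0),
    linearly interpolated on a grid of step ``grid_step_h`` over the
    reference's time span.  Each marker dimension is standardized by the
    standard deviation of its reference change course; the distance is the
    Euclidean norm divided by sqrt(#markers).  t* is the earliest grid
    minimizer; delay = t* - nominal_h.  Markers with a flat reference course
    are dropped with a warning; all dropped is an error.
    """
    import warnings

    markers = [m for m in change_vector.index if m in reference.columns]
    if not markers:
        raise ValueError("no shared markers between query and reference")
    t_ref = reference.index.to_numpy(dtype=float)
    grid = np.arange(t_ref.min(), t_ref.max() + grid_step_h / 2, grid_step_h)

    ref_change = {}
    sds = {}
    for m in markers:
        vals = np.interp(grid, t_ref, reference[m].to_numpy(dtype=float))
        change = vals - vals[0]
        sd = change.std()
        if sd == 0:
            warnings.warn(f"marker {m} has a flat reference course; dropped", stacklevel=2)
            continue
        ref_change[m] = change
        sds[m] = sd
    if not ref_change:
        raise ValueError("all markers have flat reference courses")
    used = list(ref_change)

    q = change_vector[used].to_numpy(dtype=float)
    sd_vec = np.array([sds[m] for m in used])
    ref_mat = np.column_stack([ref_change[m] for m in used])  # grid x markers
    diff = (ref_mat - q[None, :]) / sd_vec[None, :]
    d = np.sqrt((diff**2).sum(axis=1)) / np.sqrt(len(used))

    i_star = int(np.argmin(d))  # argmin returns the earliest on exact ties
    t_star = float(grid[i_star])
    span = d.max() - d.min()
    rescaled = (d - d.min()) / span if span > 0 else np.zeros_like(d)
    curve = pd.DataFrame({"time_h": grid, "distance": rescaled})
    return DelayEstimate(
        t_star=t_star,
        delta_h=t_star - nominal_h,
        curve=curve,
        d_min=float(d[i_star]),
        markers_used=used,
    )


@dataclass
class SlopeDistribution:
    """Per-gene regulation slopes under a stated selection rule."""

    slopes: pd.Series
    selection: str
    excluded: list[str]  # genes dropped for |wild-type change| <= epsilon

    @property
    def median(self) -> float:
        return float(self.slopes.median())


def regulation_slopes(
    wt_fc: pd.DataFrame,
    mut_fc: pd.DataFrame,
    selection: str | list[str] = "top_down",
    n_top: int = 100,
    epsilon: float = SLOPE_EPSILON,
) -> SlopeDistribution:
    """Slopes of regulation s_g = mutant log2 change / wild-type log2 change.

    ``selection`` is "top_down" (the n_top genes with the most negative
    wild-type log2fc), "top_up" (most positive), or an explicit gene list
    (e.g. the naive marker panel).  Genes with |wild-type change| <=
    ``epsilon`` are excluded and reported.
    """
    shared = wt_fc.index.intersection(mut_fc.index)
    wt = wt_fc.loc[shared, "log2fc"]
    mut = mut_fc.loc[shared, "log2fc"]

    if isinstance(selection, str):
        if selection == "top_down":
            genes = list(wt.nsmallest(n_top).index)
        elif selection == "top_up":
            genes = list(wt.nlargest(n_top).index)
        else:
            raise ValueError(f"unknown selection {selection!r}")
        label = selection
    else:
        genes = [g for g in selection if g in shared]
        missing = [g for g in selection if g not in shared]
        if missing:
            raise ValueError(f"selection genes absent from tables: {missing}")
        label = "explicit"
    if not genes:
        raise ValueError("empty selection")

    wt_sel = wt[genes]
    excluded = list(wt_sel.index[wt_sel.abs() <= epsilon])
    kept = [g for g in genes if g not in excluded]
    if not kept:
        raise ValueError("all selected genes have near-zero wild-type change")
    slopes = mut[kept] / wt[kept]
    slopes.name = "slope"
    return SlopeDistribution(slopes=slopes, selection=label, excluded=excluded)


@dataclass
class RatioModeResult:
    """Linear-scale fold-change ratios and their KDE mode."""

    ratios: pd.Series
    mode: float
    direction: str
    bandwidth: float


def fc_ratio_mode(
    wt_fc: pd.DataFrame,
    mut_fc: pd.DataFrame,
    target_set: GeneSet,
    direction: str = "up",
    min_genes: int = 10,
    grid_points: int = 512,
) -> RatioModeResult:
    """Mode of the linear-scale mutant/wild-type fold-change ratio.

    r_g = 2**(log2fc_mut - log2fc_wt) over the target genes of the stated
    direction; the mode is the argmax of a Gaussian KDE (Silverman
    bandwidth) evaluated on a ``grid_points``-point grid spanning
    [min r, max r].
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    genes = target_set.up if direction == "up" else target_set.down
    genes = [g for g in genes if g in wt_fc.index and g in mut_fc.index]
    if len(genes) < min_genes:
        raise ValueError(
            f"only {len(genes)} genes in the {direction} set; need >= {min_genes}"
        )
    r = np.power(2.0, mut_fc.loc[genes, "log2fc"] - wt_fc.loc[genes, "log2fc"])
    r.name = "ratio"
    if float(r.max()) == float(r.min()):
        # degenerate: all ratios identical; the mode is that value
        return RatioModeResult(ratios=r, mode=float(r.iloc[0]), direction=direction, bandwidth=0.0)
    kde = stats.gaussian_kde(r.to_numpy(), bw_method="silverman")
    grid = np.linspace(float(r.min()), float(r.max()), grid_points)
    dens = kde(grid)
    mode = float(grid[int(np.argmax(dens))])
    bw = float(kde.factor * r.std(ddof=1))
    return RatioModeResult(ratios=r, mode=mode, direction=direction, bandwidth=bw)
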
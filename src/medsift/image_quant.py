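"""Colony counting and intensity-threshold cell-type classification.

Colony counting mirrors a standard particle-analysis pipeline: large-scale
background subtraction (Gaussian high-pass), Gaussian blur, Otsu threshold,
connected components (8-connectivity), then area and circularity filters,
with circularity = 4*pi*A/P^2 computed from the Crofton perimeter.  Counts
are normalized to the mean of a control condition.

Cell classification applies per-channel intensity thresholds to segmented-
nucleus mean intensities after dropping nuclei smaller than 40 square
microns, and reports class proportions with s.e.m. across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure


@dataclass
class ColonyCountResult:
    """Accepted-colony count with per-component evidence."""

    count: int
    mask: np.ndarray  # boolean mask of accepted components
    components: pd.DataFrame  # label, area, circularity, accepted
    threshold: float  # Otsu cut on the processed image


def count_colonies(
    image: np.ndarray,
    blur_sigma: float = 2.0,
    area_range: tuple[float, float] = (50.0, 5000.0),
    circularity_range: tuple[float, float] = (0.6, 1.0),
    background_scale: float | None = None,
) -> ColonyCountResult:
    """Count colony-like bright components in a grayscale image.

    ``background_scale`` is the Gaussian high-pass scale; by default it is
    10x the radius implied by the largest accepted area, well above any
    colony's own scale.  A blank image (no foreground after thresholding)
    yields count 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("single-channel 2-D image required")
    lo_a, hi_a = area_range
    lo_c, hi_c = circularity_range
    if lo_a > hi_a or lo_c > hi_c:
        raise ValueError("invalid filter range")

    if background_scale is None:
        # 10x the largest accepted colony radius, capped so boundary
        # artifacts of the big blur stay clear of the field's interior
        background_scale = min(10.0 * np.sqrt(hi_a / np.pi), min(img.shape) / 4.0)
    highpass = img - filters.gaussian(img, sigma=background_scale, preserve_range=True)
    smooth = filters.gaussian(highpass, sigma=blur_sigma, preserve_range=True)

    if np.ptp(smooth) == 0:
        return ColonyCountResult(
            count=0,
            mask=np.zeros_like(img, dtype=bool),
            components=pd.DataFrame(columns=["label", "area", "circularity", "accepted"]),
            threshold=float("nan"),
        )
    thr = filters.threshold_otsu(smooth)
    binary = smooth > thr
    # Otsu always returns a split, even on a colony-free noise field; accept
    # the foreground only if the split explains most of the variance
    # (between-class / total variance; noise-only fields sit near 0.6)
    w1 = binary.mean()
    if 0 < w1 < 1:
        sb = w1 * (1 - w1) * (smooth[binary].mean() - smooth[~binary].mean()) ** 2
        effectiveness = sb / smooth.var()
    else:
        effectiveness = 0.0
    if effectiveness < 0.75:
        return ColonyCountResult(
            count=0,
            mask=np.zeros_like(img, dtype=bool),
            components=pd.DataFrame(columns=["label", "area", "circularity", "accepted"]),
            threshold=float(thr),
        )
    labels = measure.label(binary, connectivity=2)  # 8-connectivity
    rows = []
    accepted_mask = np.zeros_like(binary)
    for rp in measure.regionprops(labels):
        area = float(rp.area)
        perim = float(rp.perimeter_crofton)  # 4-direction Crofton estimate
        # the Crofton estimate can undershoot the true perimeter on smooth
        # rasterized shapes, pushing 4*pi*A/P^2 slightly above 1; clamp
        circ = min(4 * np.pi * area / perim**2, 1.0) if perim > 0 else 0.0
        ok = (lo_a <= area <= hi_a) and (lo_c <= circ <= hi_c)
        rows.append({"label": rp.label, "area": area, "circularity": circ, "accepted": ok})
        if ok:
            accepted_mask |= labels == rp.label
    components = pd.DataFrame(rows, columns=["label", "area", "circularity", "accepted"])
    return ColonyCountResult(
        count=int(components["accepted"].sum()) if len(components) else 0,
        mask=accepted_mask,
        components=components,
        threshold=float(thr),
    )


def normalize_colonies(
    counts: pd.DataFrame,
    control_condition: str,
    condition_col: str = "condition",
    count_col: str = "count",
) -> pd.DataFrame:
    """Normalize colony counts to the mean count of the control condition."""
    if control_condition not in set(counts[condition_col]):
        raise ValueError(f"control condition {control_condition!r} absent")
    ctrl_mean = counts.loc[counts[condition_col] == control_condition, count_col].mean()
    if ctrl_mean == 0:
        raise ValueError("control condition has zero mean colony count")
    out = counts.copy()
    out["normalized"] = out[count_col] / ctrl_mean
    return out


def classify_cells(
    table: pd.DataFrame,
    thresholds: dict[str, float],
    min_area: float = 40.0,
    class_map: dict[tuple[bool, ...], str] | None = None,
    area_col: str = "area_um2",
    replicate_col: str = "replicate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify cells by per-channel intensity thresholds.

    Cells with nuclear area below ``min_area`` (square microns) are dropped.
    A cell's signature is the tuple of (intensity > threshold) over the
    thresholded channels in order; ``class_map`` maps signatures to labels
    and defaults to the Epi/PrE convention for a (NANOG, SOX17)-style pair:
    (+,-) -> Epi, (-,+) -> PrE, anything else -> other.

    Returns (cell table with 'cell_class', summary with per-class mean
    proportion and s.e.m. across replicates).
    """
    channels = list(thresholds)
    if class_map is None:
        if len(channels) != 2:
            raise ValueError("default class map requires exactly two channels")
        class_map = {(True, False): "Epi", (False, True): "PrE"}
    kept = table[table[area_col] >= min_area].copy()
    if kept.empty:
        raise ValueError("no cells survive the area filter")
    sig = tuple(
        (kept[ch].to_numpy() > thresholds[ch]) for ch in channels
    )
    labels = [
        class_map.get(tuple(bool(s[i]) for s in sig), "other") for i in range(len(kept))
    ]
    kept["cell_class"] = labels

    per_rep = (
        kept.groupby([replicate_col, "cell_class"]).size().unstack(fill_value=0)
    )
    props = per_rep.div(per_rep.sum(axis=1), axis=0)
    summary = pd.DataFrame(
        {
            "mean_proportion": props.mean(axis=0),
            "sem": props.sem(axis=0, ddof=1) if len(props) > 1 else 0.0,
        }
    )
    return kept, summary


def suggest_threshold(
    intensities: np.ndarray | pd.Series,
    grid_points: int = 512,
) -> tuple[float, bool]:
    """Automatic bisecting threshold for a bimodal intensity distribution.

    Finds the deepest density minimum between the two highest modes of a
    Gaussian KDE; on a unimodal density it falls back to Otsu's threshold
    and flags the fallback.  Returns (threshold, used_fallback).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 50:
        raise ValueError("need >= 50 values")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no threshold")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    modes = interior[is_max]
    # ignore negligible tail wiggles: a mode must carry real density
    modes = modes[dens[modes] >= 0.1 * dens.max()]
    if modes.size < 2:
        counts, edges = np.histogram(x, bins=256)
        thr = filters.threshold_otsu(hist=(counts, (edges[:-1] + edges[1:]) / 2))
        return float(thr), True
    top2 = modes[np.argsort(dens[modes])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley]), False
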
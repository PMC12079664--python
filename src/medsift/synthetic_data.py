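"""Synthetic data generators with planted ground truth.

Every input the analysis stages consume can be generated here: sorted-screen
guide counts, bulk expression matrices with a planted response attenuation and
differentiation delay, sigmoidal naive-marker reference time courses,
rise-and-fall induction traces, two-component fluorescence mixtures, and
colony-assay images.  Each generator takes an explicit seed and is
bit-reproducible under it.

The screen generator models each cell's reporter log-intensity as a single
Gaussian, ``Normal(baseline + effect(gene), baseline_sd)``; a sort gate keeps
the corresponding tail fraction of the population, so per-guide selection
probabilities have a closed form (a Gaussian tail probability at the
population quantile) that tests use as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

CONTROL_GENE = "non-targeting"

# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class ScreenTruth:
    """Ground truth for a sorted-population CRISPR screen.

    ``effect`` maps gene name -> shift of the reporter log-intensity in units
    of ``baseline_sd`` times its value (signed; 0 for nulls).  Genes absent
    from the map have effect 0.  Control guides always have effect exactly 0.
    ``gates`` are (fraction, day, direction) triples; direction is "low" or
    "high".
    """

    n_genes: int
    guides_per_gene: int = 4
    n_controls: int = 1000
    effect: dict[str, float] = field(default_factory=dict)
    baseline_sd: float = 1.0
    library_dispersion: float = 0.3
    depth: int = 1_000_000
    gates: tuple = ((0.01, 6, "low"), (0.05, 6, "low"), (0.01, 9, "low"), (0.05, 9, "low"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.gates:
            raise ValueError("gate list must not be empty")
        for frac, _day, direction in self.gates:
            if not 0.0 < frac < 1.0:
                raise ValueError(f"gate fraction {frac} outside (0, 1)")
            if direction not in ("low", "high"):
                raise ValueError(f"gate direction {direction!r} must be 'low' or 'high'")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        for gene, eff in self.effect.items():
            if not np.isfinite(eff):
                raise ValueError(f"effect for {gene} is not finite")


@dataclass
class ExpressionTruth:
    """Ground truth for the bulk expression generator.

    ``attenuation`` is the global mutant response-scaling factor c in (0, 1]:
    every wild-type log2 fold change over differentiation is multiplied by c
    in the mutant.  ``delay_h`` shifts the mutant's naive-marker readout back
    along the reference time course.  ``pathway_activities`` maps pathway
    name -> planted activity of the mutant relative to the pathway-defining
    knockout.
    """

    attenuation: float = 1.0
    delay_h: float = 0.0
    pathway_activities: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation <= 0:
            raise ValueError("attenuation must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


@dataclass
class TraceTruth:
    """Ground truth for induction-trace simulation.

    A cell's fate is PrE iff its noise-free peak intensity strictly exceeds
    ``true_threshold`` (a peak exactly at the threshold is non-PrE).
    """

    n_cells: int = 100
    true_threshold: float = 500.0
    frame_interval_min: float = 10.0
    n_frames: int = 144
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenDataset:
    """Guide count table plus truth labels from :func:`simulate_screen`.

    ``counts`` has one row per guide with columns ``gene``, ``is_control``,
    ``unsorted`` and one integer count column per gate (named
    ``<direction>_<fraction>_<day>``).
    """

    counts: pd.DataFrame
    gate_columns: list[str]
    truth: ScreenTruth
    gene_effects: pd.Series


def gate_column_name(fraction: float, day: int, direction: str) -> str:
    return f"{direction}_{fraction:g}_{day}"


def _population_quantile(frac: float, mus: np.ndarray, sd: float, weights: np.ndarray) -> float:
    """Quantile q with mixture-CDF(q) = frac for a Gaussian location mixture."""

    def cdf(x: float) -> float:
        return float(np.sum(weights * stats.norm.cdf(x, loc=mus, scale=sd)))

    lo = float(mus.min() - 10 * sd)
    hi = float(mus.max() + 10 * sd)
    return float(optimize.brentq(lambda x: cdf(x) - frac, lo, hi, xtol=1e-12))


def simulate_screen(truth: ScreenTruth) -> ScreenDataset:
    """Simulate guide counts for an unsorted reference and each sort gate.

    Cells carrying a guide for gene g have reporter log-intensity
    ``Normal(effect_g * baseline_sd, baseline_sd)`` (baseline folded into the
    zero point).  A low gate at fraction f keeps cells below the population
    f-quantile; guide counts in the sorted pool are multinomial draws from
    library frequency times selection probability.
    """
    rng = np.random.default_rng(truth.seed)

    genes = [f"gene{i:04d}" for i in range(truth.n_genes)]
    guide_ids, guide_genes = [], []
    for g in genes:
        for j in range(truth.guides_per_gene):
            guide_ids.append(f"{g}_g{j}")
            guide_genes.append(g)
    for j in range(truth.n_controls):
        guide_ids.append(f"ctrl_{j:04d}")
        guide_genes.append(CONTROL_GENE)

    n_guides = len(guide_ids)
    is_control = np.array([g == CONTROL_GENE for g in guide_genes])

    effects = np.array(
        [0.0 if c else truth.effect.get(g, 0.0) for g, c in zip(guide_genes, is_control)]
    )
    mus = effects * truth.baseline_sd

    # library skew: lognormal abundance per guide
    lib_weights = rng.lognormal(mean=0.0, sigma=truth.library_dispersion, size=n_guides)
    lib_freq = lib_weights / lib_weights.sum()

    data = {
        "guide_id": guide_ids,
        "gene": guide_genes,
        "is_control": is_control,
        "unsorted": rng.multinomial(truth.depth, lib_freq),
    }
    gate_cols = []
    for frac, day, direction in truth.gates:
        if direction == "low":
            q = _population_quantile(frac, mus, truth.baseline_sd, lib_freq)
            p_sel = stats.norm.cdf(q, loc=mus, scale=truth.baseline_sd)
        else:
            q = _population_quantile(1.0 - frac, mus, truth.baseline_sd, lib_freq)
            p_sel = stats.norm.sf(q, loc=mus, scale=truth.baseline_sd)
        sorted_freq = lib_freq * p_sel
        sorted_freq = sorted_freq / sorted_freq.sum()
        col = gate_column_name(frac, day, direction)
        data[col] = rng.multinomial(truth.depth, sorted_freq)
        gate_cols.append(col)

    counts = pd.DataFrame(data).set_index("guide_id")
    gene_effects = pd.Series(
        {g: truth.effect.get(g, 0.0) for g in genes}, name="effect"
    )
    return ScreenDataset(counts=counts, gate_columns=gate_cols, truth=truth, gene_effects=gene_effects)


# ---------------------------------------------------------------------------
# reference time course
# ---------------------------------------------------------------------------


def simulate_reference_timecourse(
    markers: dict[str, float],
    t_max_h: float = 36.0,
    step_h: float = 2.0,
    rates: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sigmoidal naive-marker decay time course (log2 expression levels).

    ``markers`` maps marker -> level at t=0; ``rates`` maps marker -> decay
    rate r (1/h).  Each profile is ``L0 * f(r*t)`` with
    ``f(x) = 1 / (1 + x**2)``: monotone decreasing for t >= 0 with a flat
    shoulder at t=0, reaching half-maximal decline at t = 1/r, so a marker
    with rate 2r halves at half the time of one with rate r.  A rate of 0
    gives a constant profile.

    Returns a (timepoints x markers) DataFrame indexed by time in hours,
    including the t=0 row.
    """
    if step_h <= 0:
        raise ValueError("step_h must be positive")
    if rates is None:
        rates = {m: 0.1 for m in markers}
    for m, r in rates.items():
        if r < 0:
            raise ValueError(f"decay rate for {m} must be >= 0")
    missing = set(markers) - set(rates)
    if missing:
        raise ValueError(f"no rate for markers: {sorted(missing)}")

    t = np.arange(0.0, t_max_h + step_h / 2, step_h)
    values = {
        m: markers[m] / (1.0 + (rates[m] * t) ** 2) for m in markers
    }
    out = pd.DataFrame(values, index=pd.Index(t, name="time_h"))
    return out


# ---------------------------------------------------------------------------
# bulk expression
# ---------------------------------------------------------------------------


@dataclass
class BulkDataset:
    """Paired wild-type / mutant bulk expression with planted truth.

    ``wt`` and ``mut`` are linear-scale (TPM-like) gene x sample matrices;
    ``metadata`` maps sample -> (genotype, condition, replicate).  ``wt_fc``
    and ``mut_fc`` are fold-change tables for the differentiation contrast
    (24 h vs 2i) computed from replicate means of log2 expression without a
    pseudocount, so at noise_sd = 0 they equal the planted fold changes
    exactly.  ``pathway_deltas`` holds the defining-knockout delta vector per
    pathway (the footprint reference).
    """

    wt: pd.DataFrame
    mut: pd.DataFrame
    metadata: pd.DataFrame
    wt_fc: pd.DataFrame
    mut_fc: pd.DataFrame
    pathway_deltas: dict[str, pd.Series]
    truth: ExpressionTruth
    reference: pd.DataFrame


def _welch_fc_table(log2_a: pd.DataFrame, log2_b: pd.DataFrame) -> pd.DataFrame:
    """Fold-change table b - a on log2 replicate matrices (genes x reps)."""
    from statsmodels.stats.multitest import multipletests

    import warnings

    lfc = log2_b.mean(axis=1) - log2_a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows at noise_sd=0
        t, p = stats.ttest_ind(log2_b, log2_a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": lfc, "p": p, "padj": padj}, index=log2_a.index)


def simulate_bulk_expression(
    truth: ExpressionTruth,
    reference: pd.DataFrame,
    pathway_sets: dict[str, list[str]] | None = None,
    n_background: int = 400,
    wt_fc_sd: float = 1.5,
) -> BulkDataset:
    """Generate wild-type and mutant bulk expression over differentiation.

    Gene universe = naive markers (from ``reference`` columns) + pathway
    genes + ``n_background`` background genes.  On the log2 scale:

    - background genes get a wild-type differentiation fold change drawn
      ``Normal(0, wt_fc_sd)``; the mutant fold change is ``attenuation``
      times the wild-type one.
    - naive markers follow the reference time course: wild type reads it at
      24 h, the mutant at ``24 - delay_h``.
    - pathway genes get a defining-knockout delta ``Normal(0, 1.5)`` per
      gene; the mutant is offset from wild type at 24 h by
      ``activity * delta`` for its pathway's planted activity.

    Gaussian noise with sd ``noise_sd`` is added per replicate on the log2
    scale; matrices are returned on the linear scale (2**log2).
    """
    if truth.attenuation <= 0:
        raise ValueError("attenuation must be > 0")
    pathway_sets = pathway_sets or {}
    rng = np.random.default_rng(truth.seed)

    markers = list(reference.columns)
    overlap = set(markers) & {g for gs in pathway_sets.values() for g in gs}
    if overlap:
        raise ValueError(f"pathway sets overlap the naive marker panel: {sorted(overlap)}")

    background = [f"bg{i:04d}" for i in range(n_background)]
    pathway_genes = [g for gs in pathway_sets.values() for g in gs]
    genes = markers + pathway_genes + background

    def ref_at(t: float) -> pd.Series:
        idx = reference.index.to_numpy(dtype=float)
        t = float(np.clip(t, idx.min(), idx.max()))
        return pd.Series(
            {m: np.interp(t, idx, reference[m].to_numpy(dtype=float)) for m in markers}
        )

    baseline = pd.Series(rng.uniform(4.0, 9.0, size=len(genes)), index=genes)

    # planted log2 levels per (genotype, condition)
    wt_fc_bg = pd.Series(rng.normal(0.0, wt_fc_sd, size=len(background)), index=background)
    # defining knockouts shift their footprint genes coherently (nonzero mean
    # delta), keeping the activity denominator sum(delta_def) away from zero
    pathway_deltas = {
        p: pd.Series(rng.normal(1.0, 1.5, size=len(gs)), index=gs)
        for p, gs in pathway_sets.items()
    }

    lvl: dict[tuple[str, str], pd.Series] = {}
    for geno in ("wt", "mut"):
        for cond in ("2i", "N2B27_24h"):
            v = baseline.copy()
            # markers: reference course value replaces the baseline
            t_read = 0.0 if cond == "2i" else (24.0 if geno == "wt" else 24.0 - truth.delay_h)
            v[markers] = ref_at(t_read).to_numpy()
            if cond == "N2B27_24h":
                scale = 1.0 if geno == "wt" else truth.attenuation
                v[background] = baseline[background] + scale * wt_fc_bg
                for p, delta in pathway_deltas.items():
                    if geno == "mut":
                        a = truth.pathway_activities.get(p, 0.0)
                        v[delta.index] = baseline[delta.index] + a * delta
            lvl[(geno, cond)] = v

    # replicate matrices with noise
    cols, meta_rows = {}, []
    log2_reps: dict[tuple[str, str], pd.DataFrame] = {}
    for (geno, cond), v in lvl.items():
        reps = {}
        for r in range(truth.n_replicates):
            name = f"{geno}_{cond}_r{r + 1}"
            noise = rng.normal(0.0, truth.noise_sd, size=len(genes)) if truth.noise_sd > 0 else 0.0
            reps[name] = v.to_numpy() + noise
            meta_rows.append({"sample": name, "genotype": geno, "condition": cond, "replicate": r + 1})
        log2_reps[(geno, cond)] = pd.DataFrame(reps, index=genes)
        cols.update({k: np.power(2.0, c.to_numpy()) for k, c in log2_reps[(geno, cond)].items()})

    metadata = pd.DataFrame(meta_rows).set_index("sample")
    all_mat = pd.DataFrame(cols, index=genes)
    wt_cols = metadata.index[metadata.genotype == "wt"]
    mut_cols = metadata.index[metadata.genotype == "mut"]

    wt_fc = _welch_fc_table(log2_reps[("wt", "2i")], log2_reps[("wt", "N2B27_24h")])
    mut_fc = _welch_fc_table(log2_reps[("mut", "2i")], log2_reps[("mut", "N2B27_24h")])

    return BulkDataset(
        wt=all_mat[wt_cols],
        mut=all_mat[mut_cols],
        metadata=metadata,
        wt_fc=wt_fc,
        mut_fc=mut_fc,
        pathway_deltas=pathway_deltas,
        truth=truth,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# induction traces
# ---------------------------------------------------------------------------


def simulate_traces(truth: TraceTruth) -> pd.DataFrame:
    """Rise-and-fall induction traces with fate labels.

    Each cell's noise-free trace is a Gaussian bump
    ``A * exp(-(t - t_peak)^2 / (2 w^2)) + b`` whose peak ``A + b`` spans the
    fate threshold across cells; fate is "PrE" iff the noise-free peak
    strictly exceeds ``true_threshold``, "other" otherwise.  Returns a
    long-format DataFrame (cell_id, frame, time_min, intensity, fate) with
    the noise-free peak in column ``true_peak``.
    """
    rng = np.random.default_rng(truth.seed)
    t = np.arange(truth.n_frames) * truth.frame_interval_min
    total = t[-1] if truth.n_frames > 1 else 1.0

    rows = []
    fates = []
    for i in range(truth.n_cells):
        baseline = rng.uniform(20.0, 60.0)
        amp = rng.uniform(0.2, 1.8) * truth.true_threshold
        peak_time = rng.uniform(0.35, 0.65) * total
        width = rng.uniform(0.10, 0.20) * total
        clean = amp * np.exp(-((t - peak_time) ** 2) / (2 * width**2)) + baseline
        peak = float(clean.max())
        fate = "PrE" if peak > truth.true_threshold else "other"
        fates.append(fate)
        noisy = clean + (rng.normal(0.0, truth.noise_sd, size=t.size) if truth.noise_sd > 0 else 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": f"cell{i:04d}",
                    "frame": np.arange(truth.n_frames),
                    "time_min": t,
                    "intensity": noisy,
                    "fate": fate,
                    "true_peak": peak,
                }
            )
        )
    if len(set(fates)) < 2:
        raise ValueError(
            "both fates must be represented; adjust true_threshold relative to amplitudes"
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fluorescence mixtures
# ---------------------------------------------------------------------------


def simulate_mixture(
    n_per_component: tuple[int, int],
    means: tuple[float, float],
    sds: tuple[float, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Two-component lognormal intensity mixture with true labels.

    ``means`` and ``sds`` are on the log10-intensity scale.  Returns a
    DataFrame (intensity, log10_intensity, true_component) with components
    numbered by the order given.
    """
    if len(means) != 2 or len(n_per_component) != 2 or len(sds) != 2:
        raise ValueError("exactly two components required")
    if means[0] == means[1] and sds[0] == sds[1]:
        raise ValueError("components with equal means and sds are unidentifiable")
    rng = np.random.default_rng(seed)
    logs, labels = [], []
    for k, (n, mu, sd) in enumerate(zip(n_per_component, means, sds)):
        logs.append(rng.normal(mu, sd, size=n))
        labels.append(np.full(n, k))
    log10 = np.concatenate(logs)
    return pd.DataFrame(
        {
            "intensity": np.power(10.0, log10),
            "log10_intensity": log10,
            "true_component": np.concatenate(labels),
        }
    )


# ---------------------------------------------------------------------------
# colony images
# ---------------------------------------------------------------------------


def _ellipse_circularity(a: float, b: float) -> float:
    """4*pi*A/P^2 with Ramanujan's perimeter approximation."""
    area = np.pi * a * b
    h = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    return float(4 * np.pi * area / perim**2)


def simulate_colony_image(
    n_colonies: int,
    radius_range: tuple[float, float] = (8.0, 16.0),
    shape: str = "disk",
    image_size: tuple[int, int] = (512, 512),
    noise_sd: float = 0.02,
    background_gradient: float = 0.0,
    axis_ratio: float = 1.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Grayscale colony-assay image with non-overlapping colonies.

    Colonies are bright (intensity 0.8) disks, or axis-aligned ellipses when
    ``shape='ellipse'`` (minor axis = radius, major = radius*axis_ratio), on
    a dark background (0.1) with optional linear gradient and Gaussian pixel
    noise.  Placement is rejection-sampled; failure to place all colonies
    without overlap within ``max_tries`` raises.  Returns the float image in
    [0, ~1] and a truth table (cy, cx, radius, area, circularity).
    """
    if shape not in ("disk", "ellipse"):
        raise ValueError("shape must be 'disk' or 'ellipse'")
    rng = np.random.default_rng(seed)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), 0.1)
    if background_gradient:
        img += background_gradient * (xx / max(w - 1, 1))

    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)
    truth_rows = []
    tries = 0
    while len(placed) < n_colonies:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_colonies} non-overlapping colonies in {max_tries} tries"
            )
        r = rng.uniform(*radius_range)
        r_major = r * (axis_ratio if shape == "ellipse" else 1.0)
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r_major + 2, w - r_major - 2)
        if any(np.hypot(cy - py, cx - px) < r_major + pr + 2 for py, px, pr in placed):
            continue
        placed.append((cy, cx, r_major))
        if shape == "disk":
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            area = np.pi * r**2
            circ = 1.0
        else:
            mask = ((yy - cy) / r) ** 2 + ((xx - cx) / r_major) ** 2 <= 1.0
            area = np.pi * r * r_major
            circ = _ellipse_circularity(r_major, r)
        img[mask] = 0.8
        truth_rows.append(
            {"cy": cy, "cx": cx, "radius": r, "area": area, "circularity": circ}
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = pd.DataFrame(
        truth_rows, columns=["cy", "cx", "radius", "area", "circularity"]
    )
    return img, truth
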
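"""Fate prediction from induction traces and mixture-model genotype gating.

Traces (one fluorescence value per 10-min frame) are smoothed with a
centered 7-frame rolling average; a scalar feature (the smoothed peak by
default) feeds a ROC analysis whose operating point is chosen by Youden's
J = sensitivity + specificity - 1.  Genotype gating fits a two-component
Gaussian mixture to log10 fluorescence intensities by EM and assigns a cell
only when its maximum posterior reaches 0.85, leaving cells between the
populations unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# trace smoothing and features
# ---------------------------------------------------------------------------


def smooth_trace(values: np.ndarray | pd.Series, window: int = 7) -> np.ndarray:
    """Centered rolling mean; edges use shrinking windows.

    ``window`` must be odd; a window of 1 is the identity.  The trace must
    be at least ``window`` frames long.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    x = np.asarray(values, dtype=float)
    if x.size < window:
        raise ValueError(f"trace length {x.size} shorter than window {window}")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def smooth_traces(traces: pd.DataFrame, window: int = 7) -> pd.DataFrame:
    """Smooth every cell's trace in a long-format table (adds 'smoothed')."""
    out = traces.sort_values(["cell_id", "frame"]).copy()
    out["smoothed"] = out.groupby("cell_id")["intensity"].transform(
        lambda s: smooth_trace(s.to_numpy(), window)
    )
    return out


def trace_feature(traces: pd.DataFrame, feature: str = "peak") -> pd.Series:
    """Per-cell scalar from smoothed traces.

    'peak' is the maximum of the smoothed trace; 'end_of_induction' is its
    final value.  Requires a 'smoothed' column (see :func:`smooth_traces`).
    """
    if "smoothed" not in traces.columns:
        raise ValueError("traces must be smoothed first (missing 'smoothed' column)")
    g = traces.groupby("cell_id")["smoothed"]
    if feature == "peak":
        return g.max()
    if feature == "end_of_induction":
        return g.last()
    raise ValueError(f"unknown feature {feature!r}")


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """ROC curve, AUC, and the Youden-optimal threshold.

    Prediction rule: positive (PrE) when feature > threshold.  ``points``
    is ordered by increasing false-positive rate from (0, 0) to (1, 1);
    ``auc`` is its trapezoidal area.  On ties in J the lowest threshold is
    reported.
    """

    points: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    threshold: float
    j: float


def roc_youden(
    features: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    positive: str = "PrE",
) -> RocResult:
    """ROC over all distinct feature values as candidate thresholds.

    Sensitivity and specificity come from the rule feature > threshold; the
    optimal threshold maximizes J = sensitivity + specificity - 1.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # descending distinct thresholds; curve runs from (0,0) to (1,1)
    thresholds = np.unique(x)[::-1]
    tpr = np.array([(x[y] > t).sum() / n_pos for t in thresholds])
    fpr = np.array([(x[~y] > t).sum() / n_neg for t in thresholds])
    # bracket with the all-negative and all-positive operating points
    t_all = np.concatenate([[np.inf], thresholds, [-np.inf]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])

    auc = float(np.trapezoid(tpr, fpr))
    j_vals = tpr - fpr
    best_j = float(j_vals.max())
    # finite candidates achieving max J; lowest threshold on ties
    finite = np.isfinite(t_all)
    achieving = t_all[finite & (j_vals >= best_j - 1e-15)]
    threshold = float(achieving.min()) if achieving.size else float(t_all[int(np.argmax(j_vals))])

    points = pd.DataFrame({"threshold": t_all, "fpr": fpr, "tpr": tpr})
    return RocResult(points=points, auc=auc, threshold=threshold, j=best_j)


# ---------------------------------------------------------------------------
# Gaussian-mixture genotype gating
# ---------------------------------------------------------------------------


@dataclass
class MixtureAssignment:
    """Two-component mixture fit on log10 intensity plus gated assignments.

    Components are reported in ascending order of mean.  ``assignment`` is
    0 or 1 for cells whose maximum posterior reaches the certainty floor,
    -1 (unassigned) otherwise.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    posteriors: pd.DataFrame  # columns: p0, p1
    assignment: np.ndarray
    log_likelihood: float
    n_iter: int


def _em_gmm_1d(
    x: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int]:
    """Two-component 1-D Gaussian mixture by EM.

    Means initialize at the 25th/75th percentiles, both variances at the
    pooled variance, weights at 1/2.  Convergence on the mean log-likelihood
    improvement; vanishing component variance raises.
    """
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    var = np.full(2, max(x.var(), 1e-12))
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - (x[:, None] - mu[None, :]) ** 2 / (2 * var[None, :])
        )
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        resp = np.exp(log_comp - lse[:, None])
        ll = float(lse.mean())
        # M step
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise RuntimeError("EM degenerate: a component lost all responsibility")
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if (var < 1e-12).any():
            raise RuntimeError(
                f"EM degenerate: vanishing variance (means {mu}, weights {w})"
            )
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    # final responsibilities under converged parameters
    log_comp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi * var)[None, :]
        - (x[:, None] - mu[None, :]) ** 2 / (2 * var[None, :])
    )
    m = log_comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    resp = np.exp(log_comp - lse[:, None])
    return mu, np.sqrt(var), w, resp, float(lse.mean()), n_iter


def gmm_assign(
    intensities: pd.Series | np.ndarray,
    posterior_min: float = 0.85,
    seed: int = 0,
) -> MixtureAssignment:
    """Gate cells into two genotype populations by fluorescence intensity.

    Fits a two-component Gaussian mixture on log10 intensity (deterministic
    EM from percentile initialization; ``seed`` reserved for future
    stochastic restarts).  A cell is assigned to its maximum-posterior
    component iff that posterior is >= ``posterior_min``; cells between the
    populations stay unassigned (-1).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 20:
        raise ValueError("need >= 20 cells to fit the mixture")
    if (x <= 0).any():
        raise ValueError("intensities must be positive")
    logx = np.log10(x)
    mu, sd, w, resp, ll, n_iter = _em_gmm_1d(logx)
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    resp = resp[:, order]
    best = resp.argmax(axis=1)
    assignment = np.where(resp.max(axis=1) >= posterior_min, best, -1)
    idx = intensities.index if isinstance(intensities, pd.Series) else pd.RangeIndex(x.size)
    posteriors = pd.DataFrame({"p0": resp[:, 0], "p1": resp[:, 1]}, index=idx)
    return MixtureAssignment(
        means=mu,
        sds=sd,
        weights=w,
        posteriors=posteriors,
        assignment=assignment,
        log_likelihood=ll,
        n_iter=n_iter,
    )
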
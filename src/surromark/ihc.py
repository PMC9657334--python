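"""Tissue-microarray score analysis: composite scoring, positivity calling,
inter-marker regression and group comparisons.

A tumor/marker pair is summarised by a composite score on 0–8: an
Allred-style 0–5 bin of the proportion of positive cells plus a continuous
0–3 staining-intensity component. Positivity is called as score >= cut-off,
with cut-offs either fixed (clinical convention, e.g. >= 4 for ER staining)
or calibrated from the trough of the bimodal score histogram
(:func:`surromark.mixture.trough_cutoff_from_scores`).

Group comparisons use Kruskal–Wallis with tie correction followed by Dunn's
pairwise z-tests; inter-marker agreement uses ordinary least squares of one
marker's scores on another's.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, RangeError, StatisticError
from .io import IHCTable

log = logging.getLogger(__name__)

#: Allred-style proportion bin edges: bin b applies when p >= edge[b].
#: Override via the ``bin_edges`` argument of :func:`composite_score`.
DEFAULT_PROPORTION_BIN_EDGES = (0.0, 1e-9, 0.01, 0.10, 1 / 3, 2 / 3)

AGGREGATION_RULES = ("mean", "median", "max")


def proportion_bin(proportion: float, bin_edges=DEFAULT_PROPORTION_BIN_EDGES) -> int:
    """Bin a proportion of positive cells onto the 0–5 scale.

    Default edges: 0 → 0; (0, 1%) → 1; [1%, 10%) → 2; [10%, 1/3) → 3;
    [1/3, 2/3) → 4; >= 2/3 → 5.
    """
    if not 0.0 <= proportion <= 1.0:
        raise RangeError(f"proportion_positive={proportion} outside [0, 1]")
    b = 0
    for i, edge in enumerate(bin_edges):
        if proportion >= edge:
            b = i
    return b


@dataclass
class CompositeScore:
    """Composite IHC score: proportion bin (0–5) + intensity (0–3) = 0–8."""

    tumor_id: str
    marker: str
    proportion_bin: int
    intensity_component: float
    total: float
    n_replicates_aggregated: int = 1


def composite_score(
    proportion_positive: float,
    intensity: float,
    bin_edges=DEFAULT_PROPORTION_BIN_EDGES,
) -> tuple[int, float]:
    """Compute (proportion_bin, total) for one stained core or tumor.

    Intensity is kept continuous in [0, 3] (image-analysis tools emit mean
    intensities); only the proportion is binned. Maximum total is 8.
    """
    if not 0.0 <= intensity <= 3.0:
        raise RangeError(f"intensity={intensity} outside [0, 3]")
    b = proportion_bin(proportion_positive, bin_edges)
    return b, float(b + intensity)


def aggregate_replicates(
    ihc: IHCTable,
    rule: str = "mean",
    bin_edges=DEFAULT_PROPORTION_BIN_EDGES,
) -> pd.DataFrame:
    """Aggregate replicate cores and score each (tumor, marker) pair.

    Raw (proportion, intensity) values are aggregated across replicates
    *before* binning (less quantization noise than averaging bins), by
    ``rule`` in {mean, median, max}. Returns a DataFrame with one row per
    (tumor_id, marker): proportion_bin, intensity_component, total,
    n_replicates_aggregated.
    """
    if rule not in AGGREGATION_RULES:
        raise ParameterError(f"rule must be one of {AGGREGATION_RULES}, got {rule!r}")
    agg = ihc.data.groupby(["tumor_id", "marker"], sort=True).agg(
        proportion_positive=("proportion_positive", rule),
        intensity=("intensity", rule),
        n_replicates_aggregated=("proportion_positive", "size"),
    ).reset_index()
    bins, totals = [], []
    for p, i in zip(agg["proportion_positive"], agg["intensity"]):
        b, t = composite_score(p, i, bin_edges)
        bins.append(b)
        totals.append(t)
    agg["proportion_bin"] = bins
    agg["intensity_component"] = agg["intensity"]
    agg["total"] = totals
    return agg[["tumor_id", "marker", "proportion_bin", "intensity_component",
                "total", "n_replicates_aggregated"]]


def score_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot aggregated scores to tumors × markers of total scores."""
    return scores.pivot(index="tumor_id", columns="marker", values="total")


def call_marker_status(score, cutoff: float):
    """Positive iff score >= cutoff (the IHC convention; both on [0, 8])."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0) or np.any(arr > 8):
        raise RangeError("scores must lie in [0, 8]")
    if not 0.0 <= cutoff <= 8.0:
        raise RangeError(f"cutoff={cutoff} outside [0, 8]")
    result = arr >= cutoff
    return bool(result) if np.isscalar(score) else result


@dataclass
class GroupComparison:
    """Kruskal–Wallis omnibus plus Dunn's pairwise post-hoc tests."""

    groups: list[str]
    kw_H: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, dunn_z, p_unadjusted, adjusted_p


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray, adjust: str) -> pd.DataFrame:
    """Dunn's z-statistics on mean ranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)),
    T = Σ(t³ − t) / (12(N − 1)) over tie groups.
    """
    N = values.size
    ranks = stats.rankdata(values)
    group_names = sorted(pd.unique(labels))
    mean_ranks = {g: ranks[labels == g].mean() for g in group_names}
    sizes = {g: int((labels == g).sum()) for g in group_names}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(group_names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "dunn_z": float(z),
                     "p_unadjusted": float(min(p, 1.0))})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "bonferroni":
        df["adjusted_p"] = np.minimum(df["p_unadjusted"] * m, 1.0)
    elif adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(df["p_unadjusted"], method="holm")
        df["adjusted_p"] = adj
    else:
        raise ParameterError(f"adjust must be 'bonferroni' or 'holm', got {adjust!r}")
    return df


def compare_groups(scores, groups, adjust: str = "bonferroni") -> GroupComparison:
    """Compare score distributions across labeled tumor groups.

    ``scores`` and ``groups`` are aligned mappings/Series keyed by tumor.
    Requires >= 2 groups with >= 2 tumors each and non-constant scores.
    """
    s = pd.Series(scores, dtype=float)
    g = pd.Series(groups).reindex(s.index)
    if g.isna().any():
        missing = list(g.index[g.isna()])
        raise ParameterError(f"tumors without group labels: {missing[:5]}")
    values = s.to_numpy()
    labels = g.astype(str).to_numpy()
    group_names = sorted(pd.unique(labels))
    if len(group_names) < 2:
        raise ParameterError("need at least 2 groups")
    for name in group_names:
        if (labels == name).sum() < 2:
            raise ParameterError(f"group {name!r} has fewer than 2 tumors")
    if np.unique(values).size == 1:
        raise StatisticError("all scores identical; Kruskal-Wallis H undefined")
    samples = [values[labels == name] for name in group_names]
    H, p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(values, labels, adjust)
    return GroupComparison(groups=group_names, kw_H=float(H), kw_p=float(p),
                           pairwise=pairwise)


@dataclass
class RegressionFit:
    """Ordinary least squares of one marker's scores on another's."""

    marker_x: str
    marker_y: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def pairwise_marker_regression(scores_x, scores_y,
                               marker_x: str = "x", marker_y: str = "y") -> RegressionFit:
    """OLS of y-scores on x-scores over shared tumors; reports R²."""
    sx = pd.Series(scores_x, dtype=float)
    sy = pd.Series(scores_y, dtype=float)
    shared = sx.index.intersection(sy.index)
    if len(shared) < 3:
        raise ParameterError(f"need >= 3 shared tumors, got {len(shared)}")
    x = sx.loc[shared].to_numpy()
    y = sy.loc[shared].to_numpy()
    if np.var(x) == 0:
        raise StatisticError("zero variance in x scores; regression undefined")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.var(y) == 0 else float(res.rvalue**2)
    return RegressionFit(
        marker_x=marker_x, marker_y=marker_y,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=r2, n=int(len(shared)),
    )
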
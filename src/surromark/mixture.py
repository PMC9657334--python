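"""Low/high classification of a bimodal marker distribution.

Many luminal markers (ESR1 expression, ER immunostaining scores) split a
tumor cohort into a low and a high mode. This module formalises the visual
low/high split as a two-component univariate Gaussian mixture fitted by EM,
with BIC model selection against a single Gaussian deciding whether the
marker is bimodal at all. The decision boundary is the point between the
component means where posterior membership is equal.

For composite IHC scores on the 0–8 scale, :func:`trough_cutoff_from_scores`
instead locates the trough of a kernel-density estimate between the two
dominant modes, matching how score cut-offs are read off a bimodal
histogram in practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, ParameterError, StateError

log = logging.getLogger(__name__)

_MIN_POINTS = 20
# variance floor relative to total variance, guards EM against collapse
_VAR_FLOOR_FRAC = 1e-6


@dataclass
class MixtureFit:
    """Result of a two-component Gaussian mixture fit to one marker.

    ``threshold`` is present only when the two-component model both converged
    and is preferred by BIC; otherwise classification is refused and the
    marker should be treated as unimodal.
    """

    means: tuple[float, float]           # sorted ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float
    bic_one_component: float
    bic_two_component: float
    threshold: float | None
    converged: bool
    n_iterations: int
    loglik_trace: tuple[float, ...] = ()

    @property
    def is_bimodal(self) -> bool:
        return self.threshold is not None

    def to_dict(self) -> dict:
        return {
            "means": list(self.means),
            "sds": list(self.sds),
            "weights": list(self.weights),
            "log_likelihood": self.log_likelihood,
            "bic_one_component": self.bic_one_component,
            "bic_two_component": self.bic_two_component,
            "threshold": self.threshold,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


def _loglik(x, means, sds, weights):
    comp = np.stack([
        np.log(weights[k]) + stats.norm.logpdf(x, means[k], sds[k])
        for k in range(2)
    ])
    m = comp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(comp - m).sum(axis=0))))


def _em(x, means, sds, weights, max_iter, tol, var_floor):
    """Run EM from one start; returns (params, loglik, trace, converged, n_iter)."""
    n = x.size
    prev = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        logp = np.stack([
            np.log(weights[k]) + stats.norm.logpdf(x, means[k], sds[k])
            for k in range(2)
        ])
        m = logp.max(axis=0)
        ll = float(np.sum(m + np.log(np.exp(logp - m).sum(axis=0))))
        trace.append(ll)
        resp = np.exp(logp - (m + np.log(np.exp(logp - m).sum(axis=0))))
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp @ x) / nk
        var = np.array([
            float(resp[k] @ (x - means[k]) ** 2) / nk[k] for k in range(2)
        ])
        sds = np.sqrt(np.maximum(var, var_floor))
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
    ll = _loglik(x, means, sds, weights)
    trace.append(ll)
    return (means, sds, weights), ll, trace, converged, it


def _posterior_boundary(means, sds, weights):
    """Point between the means where the two posteriors are equal.

    Solves w1·N(x|m1,s1) = w2·N(x|m2,s2), a quadratic in x; returns the root
    strictly between the means, falling back to a grid argmin of the
    posterior gap when no analytic root lies in the interval.
    """
    (m1, m2), (s1, s2), (w1, w2) = means, sds, weights
    if not m1 < m2:
        return None
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = (m2**2 / s2**2 - m1**2 / s1**2
         + 2.0 * (math.log(w1 / w2) + math.log(s2 / s1)))
    roots = []
    if abs(a) < 1e-12:
        if abs(b) > 1e-12:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    if inside:
        return float(min(inside, key=lambda r: abs(r - 0.5 * (m1 + m2))))
    grid = np.linspace(m1, m2, 2001)[1:-1]
    gap = np.abs(
        np.log(w1) + stats.norm.logpdf(grid, m1, s1)
        - np.log(w2) - stats.norm.logpdf(grid, m2, s2)
    )
    return float(grid[int(np.argmin(gap))])


def fit_two_component_mixture(
    values,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to one marker's values.

    EM is started deterministically from a median split, plus one random
    restart drawn from ``seed``; the start with the higher final likelihood
    wins. Model selection against a single Gaussian uses BIC (two parameters
    for one component, five for two). The low/high ``threshold`` — the equal
    posterior point between the means — is set only when the two-component
    model is preferred and EM converged.

    Raises
    ------
    DataError
        Fewer than 20 finite values, or zero variance.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = x.size
    if n < _MIN_POINTS:
        raise DataError(f"need at least {_MIN_POINTS} finite values, got {n}")
    total_var = float(np.var(x))
    if total_var <= 0:
        raise DataError("values have zero variance; no mixture is identifiable")
    var_floor = max(total_var * _VAR_FLOOR_FRAC, 1e-300)

    starts = []
    # deterministic start: split at the sample median
    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = np.sort(x)[: n // 2], np.sort(x)[n // 2:]
    starts.append((
        np.array([lo.mean(), hi.mean()]),
        np.sqrt(np.maximum([lo.var(), hi.var()], var_floor)),
        np.array([lo.size / n, hi.size / n]),
    ))
    # one random restart from the seed
    rng = np.random.default_rng(seed)
    pick = rng.choice(n, size=2, replace=False)
    mu = np.sort(x[pick])
    starts.append((
        mu.astype(float),
        np.full(2, math.sqrt(total_var)),
        np.array([0.5, 0.5]),
    ))

    best = None
    for means0, sds0, weights0 in starts:
        params, ll, trace, conv, it = _em(
            x, means0.copy(), sds0.copy(), weights0.copy(), max_iter, tol, var_floor
        )
        if best is None or ll > best[1]:
            best = (params, ll, trace, conv, it)
    (means, sds, weights), ll2, trace, converged, n_iter = best

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    # single-Gaussian reference model
    mu0, sd0 = float(x.mean()), math.sqrt(total_var)
    ll1 = float(stats.norm.logpdf(x, mu0, sd0).sum())
    bic1 = 2 * math.log(n) - 2 * ll1
    bic2 = 5 * math.log(n) - 2 * ll2

    threshold = None
    if converged and bic2 < bic1:
        threshold = _posterior_boundary(tuple(means), tuple(sds), tuple(weights))
    if not converged:
        log.warning("EM did not converge in %d iterations; no threshold set", max_iter)

    return MixtureFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        log_likelihood=ll2,
        bic_one_component=bic1,
        bic_two_component=bic2,
        threshold=threshold,
        converged=converged,
        n_iterations=n_iter,
        loglik_trace=tuple(trace),
    )


def classify_low_high(values, fit: MixtureFit) -> np.ndarray:
    """Boolean class vector: True = high (value strictly above the threshold).

    Ties at the threshold are assigned low — the conservative convention for
    positivity calling on continuous expression values. (IHC score positivity
    uses ``>=`` on its rounded cut-off instead; see :mod:`surromark.ihc`.)
    """
    if fit.threshold is None:
        raise StateError(
            "no threshold: marker was not called bimodal "
            "(BIC preferred one component or EM failed)"
        )
    x = np.asarray(values, dtype=float)
    return x > fit.threshold


def trough_cutoff_from_scores(
    scores,
    bandwidth="auto",
    increment: float = 0.5,
    grid_size: int = 801,
) -> float:
    """Read a positivity cut-off off the trough of a bimodal score histogram.

    A Gaussian KDE (Silverman bandwidth when ``bandwidth="auto"``) is
    evaluated on [0, 8]; the cut-off is the deepest local minimum between the
    two highest local maxima, rounded **up** to the nearest score increment
    (default 0.5, the resolution of half-point composite scores).

    Raises
    ------
    DataError
        Fewer than 20 scores or fewer than 2 distinct values.
    ParameterError
        The density has no interior local minimum (unimodal): use a fixed
        cut-off instead.
    """
    x = np.asarray(scores, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < _MIN_POINTS:
        raise DataError(f"need at least {_MIN_POINTS} scores, got {x.size}")
    if np.unique(x).size < 2:
        raise DataError("scores take a single value; no trough exists")
    if bandwidth == "auto":
        kde = stats.gaussian_kde(x, bw_method="silverman")
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ParameterError("bandwidth must be positive")
        kde = stats.gaussian_kde(x, bw_method=bw / x.std(ddof=1))
    grid = np.linspace(0.0, 8.0, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    is_min = (dens[interior] <= dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    maxima = interior[is_max]
    minima = interior[is_min]
    # collapse plateaus
    maxima = maxima[np.insert(np.diff(maxima) > 1, 0, True)] if maxima.size else maxima
    minima = minima[np.insert(np.diff(minima) > 1, 0, True)] if minima.size else minima
    if maxima.size < 2 or minima.size == 0:
        raise ParameterError(
            "score density is unimodal; no trough — use a fixed cut-off"
        )
    top2 = maxima[np.argsort(dens[maxima])][-2:]
    lo_peak, hi_peak = sorted(int(i) for i in top2)
    between = minima[(minima > lo_peak) & (minima < hi_peak)]
    if between.size == 0:
        raise ParameterError(
            "no local minimum between the two dominant modes — use a fixed cut-off"
        )
    trough = float(grid[between[np.argmin(dens[between])]])
    cutoff = math.ceil(trough / increment - 1e-9) * increment
    return float(min(cutoff, 8.0))
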
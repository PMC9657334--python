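"""Subtype enrichment of a selected tumor subset.

Given a selection of samples out of a labeled population (e.g. the
reference-high / surrogate-low group within a subtyped cohort), each label
is tested for over-representation with the one-sided (upper-tail) exact
hypergeometric probability P(X >= k), and p-values are adjusted across
labels by Benjamini–Hochberg to q-values. Depletion shows up as fold
enrichment < 1 but is not separately tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError


@dataclass
class EnrichmentResult:
    """One label's over-representation in the selection.

    N: population size; K: label count in population; n: selection size;
    k: label count in selection; fold_enrichment = (k/n)/(K/N).
    """

    label: str
    population_size: int
    labeled_in_population: int
    selection_size: int
    labeled_in_selection: int
    p_value: float
    q_value: float
    fold_enrichment: float


def hypergeometric_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail exact hypergeometric probability P(X >= k)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ParameterError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    Each q >= its p, all q <= 1, and monotonicity over the p-ranking is
    enforced by the cumulative-minimum step.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.asarray(q, dtype=float)


def hypergeometric_enrichment(
    selection: Iterable[str],
    labels: Mapping[str, str],
) -> list[EnrichmentResult]:
    """Test every label for over-representation in the selection.

    ``labels`` maps every population sample to its label; ``selection`` must
    be a subset of that population (a missing sample raises ``KeyError``
    naming it). Returns one :class:`EnrichmentResult` per label, q-values
    adjusted across labels, sorted by ascending p-value.
    """
    selection = list(dict.fromkeys(selection))  # dedupe, keep order
    if not labels:
        raise DataError("label map is empty")
    for s in selection:
        if s not in labels:
            raise KeyError(f"selected sample {s!r} absent from label map")
    N = len(labels)
    n = len(selection)
    label_values = sorted({str(v) for v in labels.values()})
    pop_counts = {lab: 0 for lab in label_values}
    for v in labels.values():
        pop_counts[str(v)] += 1
    sel_counts = {lab: 0 for lab in label_values}
    for s in selection:
        sel_counts[str(labels[s])] += 1

    results = []
    pvals = []
    for lab in label_values:
        K, k = pop_counts[lab], sel_counts[lab]
        p = hypergeometric_p(N, K, n, k)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        results.append(EnrichmentResult(
            label=lab,
            population_size=N,
            labeled_in_population=K,
            selection_size=n,
            labeled_in_selection=k,
            p_value=p,
            q_value=p,  # filled below
            fold_enrichment=fold,
        ))
        pvals.append(p)
    qvals = bh_adjust(pvals)
    for res, q in zip(results, qvals):
        res.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.label))
    return results
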
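"""Statistics comparing candidate surrogate genes against a reference gene.

The central statistic is *exclusion at fixed reference specificity*: choose
the candidate-gene cut-off that captures a set fraction q (default 90%) of
reference-low samples, then measure how many reference-high samples fall at
or below that same cut-off. A good surrogate excludes the reference-low
population while sacrificing few reference-high samples. The cut-off is an
observed value (empirical inverse CDF, no interpolation) and "excluded"
means value ≤ cut-off, so the statistic is exactly reproducible by a
brute-force scan over observed values and is invariant under any strictly
increasing transform of the candidate values.

Also here: RNA-class vs clinical-status discordance, the "rescue"
cross-tabulation (how many reference-high / primary-surrogate-low samples
are called high by alternative surrogates), and the orchestration that runs
all of these for a list of candidates against one reference gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, StatisticError
from .io import NEGATIVE, POSITIVE, UNKNOWN, ClinicalTable, ExpressionMatrix
from .mixture import MixtureFit, classify_low_high, fit_two_component_mixture

log = logging.getLogger(__name__)

#: Default gene → clinical status column pairing for discordance.
DEFAULT_CLINICAL_COLUMNS = {"ESR1": "er_status", "PGR": "pr_status"}


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient of two aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise DataError(f"need at least 3 paired values, got {x.size}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise StatisticError("Pearson correlation undefined for constant vector")
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass
class ExclusionResult:
    """Candidate cut-off at fixed reference-low specificity, and its cost.

    ``threshold`` captures at least ``specificity_q`` of reference-low
    samples; ``excluded_high_fraction`` is the price paid — the fraction of
    reference-high samples also at/below the cut-off.
    """

    candidate_gene: str
    specificity_q: float
    threshold: float
    excluded_low_fraction: float
    excluded_high_fraction: float
    excluded_high_as_fraction_of_all: float
    excluded_low_as_fraction_of_all: float
    n_low: int
    n_high: int


def exclusion_at_reference_specificity(
    candidate_values,
    reference_class,
    q: float = 0.90,
    candidate_gene: str = "",
) -> ExclusionResult:
    """Cut the candidate at the smallest observed value capturing q of the
    reference-low group, and report the excluded fractions.

    ``reference_class`` is boolean (True = reference-high). A sample is
    "excluded" iff its candidate value ≤ threshold.
    """
    x = np.asarray(candidate_values, dtype=float)
    ref_high = np.asarray(reference_class, dtype=bool)
    if x.shape != ref_high.shape or x.ndim != 1:
        raise ParameterError("candidate values and reference classes must align")
    if not 0.0 < q <= 1.0:
        raise ParameterError(f"q must be in (0, 1], got {q}")
    low_vals = np.sort(x[~ref_high])
    high_vals = x[ref_high]
    n_low, n_high = low_vals.size, high_vals.size
    if n_low == 0 or n_high == 0:
        raise DataError(
            f"both reference classes must be non-empty (n_low={n_low}, n_high={n_high})"
        )
    # smallest observed value t with P_low(X <= t) >= q: the ceil(q*n_low)-th
    # order statistic of the low group (fractions only jump at low values)
    k = math.ceil(q * n_low - 1e-12)
    t = float(low_vals[k - 1])
    excluded_low = float(np.mean(low_vals <= t))
    excluded_high = float(np.mean(high_vals <= t))
    n_total = n_low + n_high
    return ExclusionResult(
        candidate_gene=candidate_gene,
        specificity_q=q,
        threshold=t,
        excluded_low_fraction=excluded_low,
        excluded_high_fraction=excluded_high,
        excluded_high_as_fraction_of_all=float(np.sum(high_vals <= t)) / n_total,
        excluded_low_as_fraction_of_all=float(np.sum(low_vals <= t)) / n_total,
        n_low=n_low,
        n_high=n_high,
    )


@dataclass
class ConcordanceResult:
    """Agreement between an RNA-derived low/high class and a clinical status."""

    marker: str
    n_compared: int
    n_discordant: int
    discordance_rate: float
    n_high_but_negative: int
    n_low_but_positive: int
    n_unknown_excluded: int


def status_discordance(rna_class, clinical_status, marker: str = "") -> ConcordanceResult:
    """Count disagreements between RNA class and ternary clinical status.

    Unknown statuses are excluded from the denominator (and counted).
    Discordance = (RNA high, status negative) or (RNA low, status positive).
    """
    rna_high = np.asarray(rna_class, dtype=bool)
    status = np.asarray(clinical_status, dtype=object)
    if rna_high.shape != status.shape:
        raise ParameterError("rna_class and clinical_status must align")
    bad = set(status) - {POSITIVE, NEGATIVE, UNKNOWN}
    if bad:
        raise ParameterError(f"invalid status values {sorted(bad)}")
    known = status != UNKNOWN
    n_compared = int(known.sum())
    if n_compared == 0:
        raise DataError("all clinical statuses unknown; discordance undefined")
    hi_neg = rna_high & (status == NEGATIVE)
    lo_pos = ~rna_high & (status == POSITIVE)
    n_disc = int(hi_neg.sum() + lo_pos.sum())
    return ConcordanceResult(
        marker=marker,
        n_compared=n_compared,
        n_discordant=n_disc,
        discordance_rate=n_disc / n_compared,
        n_high_but_negative=int(hi_neg.sum()),
        n_low_but_positive=int(lo_pos.sum()),
        n_unknown_excluded=int((~known).sum()),
    )


@dataclass
class RescueResult:
    """How often alternative surrogates call the reference-high /
    primary-surrogate-low group high anyway."""

    n_target_group: int
    per_gene_high_fraction: dict[str, float]
    union_high_fraction: float


def rescue_fraction(reference_class, primary_candidate_class, alt_gene_classes) -> RescueResult:
    """Cross-tabulate alternative surrogate calls on the discrepant group.

    The target group is reference-high & primary-candidate-low. For each
    alternative gene, report the fraction of that group classed high; the
    union fraction counts samples high for at least one alternative.
    """
    ref_high = np.asarray(reference_class, dtype=bool)
    primary_high = np.asarray(primary_candidate_class, dtype=bool)
    if ref_high.shape != primary_high.shape:
        raise ParameterError("class vectors must align")
    target = ref_high & ~primary_high
    n_target = int(target.sum())
    if n_target == 0:
        raise DataError("target group (reference-high & primary-low) has size 0")
    per_gene = {}
    any_high = np.zeros(n_target, dtype=bool)
    for gene, cls in alt_gene_classes.items():
        cls = np.asarray(cls, dtype=bool)
        if cls.shape != ref_high.shape:
            raise ParameterError(f"class vector for {gene!r} must align")
        in_group = cls[target]
        per_gene[gene] = float(in_group.mean())
        any_high |= in_group
    union = float(any_high.mean()) if per_gene else 0.0
    return RescueResult(
        n_target_group=n_target,
        per_gene_high_fraction=per_gene,
        union_high_fraction=union,
    )


@dataclass
class EvaluationReport:
    """Full candidate-vs-reference evaluation on one expression matrix."""

    reference_gene: str
    reference_fit: MixtureFit
    reference_class: np.ndarray          # True = reference-high, sample order
    table: pd.DataFrame                  # one row per candidate
    exclusions: dict[str, ExclusionResult]
    discordance: dict[str, ConcordanceResult] = field(default_factory=dict)
    rescue: RescueResult | None = None


def evaluate_candidates(
    expression: ExpressionMatrix,
    reference_gene: str,
    candidate_genes,
    clinical: ClinicalTable | None = None,
    q: float = 0.90,
    seed: int = 0,
    primary_candidate: str = "PGR",
    clinical_columns=None,
) -> EvaluationReport:
    """Run the full surrogate evaluation for one reference gene.

    Fits the reference gene's two-component mixture to derive low/high
    classes, then per candidate computes Pearson r with the reference and the
    exclusion statistic at specificity ``q``; when a clinical table is given,
    RNA/status discordance is computed for every gene with a mapped status
    column (default: ESR1 → er_status, PGR → pr_status). If
    ``primary_candidate`` is among the candidates, the rescue analysis uses
    the remaining candidates as alternatives, each classed by its own
    q-specificity cut-off.
    """
    candidate_genes = list(candidate_genes)
    for g in [reference_gene, *candidate_genes]:
        if g not in expression.data.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    if clinical_columns is None:
        clinical_columns = DEFAULT_CLINICAL_COLUMNS
    ref_values = expression.gene(reference_gene)
    fit = fit_two_component_mixture(ref_values, seed=seed)
    ref_class = classify_low_high(ref_values, fit)  # StateError if unimodal

    sample_ids = expression.sample_ids
    statuses = {}
    if clinical is not None:
        for gene, col in clinical_columns.items():
            if col in clinical.data.columns:
                statuses[gene] = clinical.status(col, sample_ids)

    exclusions: dict[str, ExclusionResult] = {}
    discordance: dict[str, ConcordanceResult] = {}
    classes: dict[str, np.ndarray] = {}
    rows = []
    if reference_gene in statuses:
        discordance[reference_gene] = status_discordance(
            ref_class, statuses[reference_gene], marker=reference_gene
        )
    for gene in candidate_genes:
        vals = expression.gene(gene)
        r = pearson_correlation(ref_values, vals)
        excl = exclusion_at_reference_specificity(vals, ref_class, q=q, candidate_gene=gene)
        exclusions[gene] = excl
        classes[gene] = vals > excl.threshold
        row = {
            "candidate": gene,
            "pearson_r": r,
            "threshold": excl.threshold,
            "excluded_low_fraction": excl.excluded_low_fraction,
            "excluded_high_fraction": excl.excluded_high_fraction,
            "excluded_high_frac_of_all": excl.excluded_high_as_fraction_of_all,
            "excluded_low_frac_of_all": excl.excluded_low_as_fraction_of_all,
            "n_low": excl.n_low,
            "n_high": excl.n_high,
            "discordance_rate": np.nan,
        }
        if gene in statuses:
            disc = status_discordance(classes[gene], statuses[gene], marker=gene)
            discordance[gene] = disc
            row["discordance_rate"] = disc.discordance_rate
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=[
            "candidate", "pearson_r", "threshold",
            "excluded_low_fraction", "excluded_high_fraction",
            "excluded_high_frac_of_all", "excluded_low_frac_of_all",
            "n_low", "n_high", "discordance_rate",
        ],
    )

    rescue = None
    if primary_candidate in classes and len(classes) > 1:
        alts = {g: c for g, c in classes.items() if g != primary_candidate}
        try:
            rescue = rescue_fraction(ref_class, classes[primary_candidate], alts)
        except DataError:
            log.warning("rescue analysis skipped: empty target group")
    return EvaluationReport(
        reference_gene=reference_gene,
        reference_fit=fit,
        reference_class=ref_class,
        table=table,
        exclusions=exclusions,
        discordance=discordance,
        rescue=rescue,
    )
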
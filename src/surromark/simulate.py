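"""Synthetic breast-tumor cohort generator with latent regulatory structure.

The generator emulates the regulatory architecture that surrogate-marker
analyses of luminal breast cancer assume: each tumor carries a subtype
(LumA, LumB, molecular apocrine, basal-like) which sets latent ER and GATA3
activities; observed log2 expression of each gene is a linear readout of
those activities plus Gaussian noise, with optional subtype-dependent
dropout (expression collapses to baseline — the mechanism behind
ESR1-high/PGR-low LumB tumors). Clinical ER/PR statuses are the true
activity-derived classes flipped with small probabilities, emulating
pathology-report misclassification. A fraction of molecular apocrine tumors
draws GATA3 activity from a high component, producing the CA12-positive,
ER-negative subset seen in real cohorts.

All randomness flows through one ``numpy`` Generator seeded from
``CohortParams.seed``; draws are consumed in a fixed documented order
(subtype → ER activity → GATA3 component → GATA3 activity → per-gene noise
and dropout in sorted gene order → status flips → HER2), so identical
parameters reproduce cohorts bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (
    NEGATIVE,
    POSITIVE,
    ClinicalTable,
    ExpressionMatrix,
    IHCTable,
)

log = logging.getLogger(__name__)

SUBTYPES = ("LumA", "LumB", "mApo", "Basal")
LUMINAL_SUBTYPES = ("LumA", "LumB")

#: Default marker → gene map for the simulated TMA arm.
DEFAULT_MARKER_GENES: Mapping[str, str] = {
    "ER": "ESR1",
    "CAXII": "CA12",
    "GATA3": "GATA3",
    "FOXA1": "FOXA1",
}


@dataclass
class GeneModel:
    """Linear-Gaussian readout of the latent activities for one gene.

    expression = baseline + er_weight·er_activity + gata3_weight·gata3_activity
    + N(0, noise_sd); with probability ``dropout_prob[subtype]`` the readout
    collapses to baseline + N(0, noise_sd) instead (dropout).
    """

    baseline: float
    er_weight: float = 0.0
    gata3_weight: float = 0.0
    noise_sd: float = 0.5
    dropout_prob: Mapping[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if self.noise_sd <= 0:
            raise ParameterError(f"gene {name}: noise_sd must be positive")
        for s, p in self.dropout_prob.items():
            if s not in SUBTYPES:
                raise ParameterError(f"gene {name}: unknown subtype {s!r}")
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"gene {name}: dropout_prob[{s}]={p} not in [0,1]")


def default_gene_models(n_decoys: int = 3) -> dict[str, GeneModel]:
    """Default gene models reproducing the luminal-marker phenomenology.

    ESR1 is strongly ER-driven (bimodal across luminal vs non-luminal);
    PGR is ER-driven but noisy, with frequent LumB dropout; CA12 has two
    drivers (ER and GATA3) and no dropout — the properties that make it the
    better ESR1 surrogate. TFF1 is a noisier ER target than GREB1. Decoy
    genes are pure noise.
    """
    models = {
        "ESR1": GeneModel(baseline=6.0, er_weight=1.5, gata3_weight=0.5, noise_sd=0.6),
        "PGR": GeneModel(
            baseline=5.0, er_weight=1.6, noise_sd=1.1,
            dropout_prob={"LumA": 0.06, "LumB": 0.30},
        ),
        "CA12": GeneModel(baseline=5.5, er_weight=0.9, gata3_weight=0.9, noise_sd=0.7),
        "TFF1": GeneModel(baseline=4.5, er_weight=1.4, noise_sd=1.5),
        "GREB1": GeneModel(baseline=5.0, er_weight=1.3, noise_sd=0.8),
        "FOXA1": GeneModel(baseline=6.5, er_weight=0.5, gata3_weight=0.9, noise_sd=0.7),
        "GATA3": GeneModel(baseline=6.0, er_weight=0.2, gata3_weight=1.3, noise_sd=0.6),
    }
    for i in range(n_decoys):
        models[f"DECOY{i + 1}"] = GeneModel(baseline=7.0, noise_sd=1.0)
    return models


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Defaults encode the study conditions: ~70% luminal prevalence, ER-status
    misclassification 5.4% and PR 13.4%, and 40% of molecular apocrine
    tumors drawing GATA3 activity from the high component.
    """

    n_samples: int = 750
    subtype_prevalence: Mapping[str, float] = field(default_factory=lambda: {
        "LumA": 0.45, "LumB": 0.25, "mApo": 0.10, "Basal": 0.20,
    })
    er_activity_means: Mapping[str, float] = field(default_factory=lambda: {
        "LumA": 3.5, "LumB": 3.0, "mApo": 0.3, "Basal": 0.0,
    })
    er_activity_sd: float = 0.5
    gata3_activity_means: Mapping[str, float] = field(default_factory=lambda: {
        "LumA": 3.0, "LumB": 2.8, "mApo": 0.2, "Basal": 0.0,
    })
    gata3_activity_sd: float = 0.5
    #: mApo samples draw GATA3 activity from a high component with this prob.
    gata3_high_mapo_fraction: float = 0.4
    mapo_gata3_high_mean: float = 2.5
    gene_models: Mapping[str, GeneModel] = field(default_factory=default_gene_models)
    status_flip_prob_er: float = 0.054
    status_flip_prob_pr: float = 0.134
    her2_positive_frac: Mapping[str, float] = field(default_factory=lambda: {
        "mApo": 0.7, "Basal": 0.1,
    })
    seed: int = 0

    def validate(self) -> None:
        prev = np.array([self.subtype_prevalence.get(s, 0.0) for s in SUBTYPES])
        if set(self.subtype_prevalence) - set(SUBTYPES):
            raise ParameterError(
                f"unknown subtypes {set(self.subtype_prevalence) - set(SUBTYPES)}"
            )
        if (prev < 0).any() or abs(prev.sum() - 1.0) > 1e-9:
            raise ParameterError("subtype_prevalence must be non-negative and sum to 1")
        if self.er_activity_sd <= 0 or self.gata3_activity_sd <= 0:
            raise ParameterError("activity sds must be positive")
        for p, name in (
            (self.gata3_high_mapo_fraction, "gata3_high_mapo_fraction"),
            (self.status_flip_prob_er, "status_flip_prob_er"),
            (self.status_flip_prob_pr, "status_flip_prob_pr"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} not in [0,1]")
        for s, p in self.her2_positive_frac.items():
            if s not in SUBTYPES or not 0.0 <= p <= 1.0:
                raise ParameterError(f"her2_positive_frac[{s}]={p} invalid")
        for name, gm in self.gene_models.items():
            gm.validate(name)


@dataclass
class SyntheticCohort:
    """A generated cohort: observed tables plus per-sample ground truth."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    ihc: IHCTable
    truth: pd.DataFrame  # index: sample_id
    params: CohortParams


def _gene_drive(gm: GeneModel, er_act: np.ndarray, g3_act: np.ndarray) -> np.ndarray:
    return gm.baseline + gm.er_weight * er_act + gm.gata3_weight * g3_act


def _global_midpoint(params: CohortParams, gm: GeneModel) -> float:
    """Midpoint of the expected activity-driven means across subtypes.

    The mApo GATA3 mixture contributes both of its components as separate
    states, so the midpoint reflects the full range of population means.
    """
    states = []
    for s in SUBTYPES:
        er_m = params.er_activity_means[s]
        if s == "mApo":
            for g3_m in (params.gata3_activity_means[s], params.mapo_gata3_high_mean):
                states.append(gm.baseline + gm.er_weight * er_m + gm.gata3_weight * g3_m)
        else:
            g3_m = params.gata3_activity_means[s]
            states.append(gm.baseline + gm.er_weight * er_m + gm.gata3_weight * g3_m)
    return 0.5 * (min(states) + max(states))


def generate_cohort(params: CohortParams | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort (expression, clinical, IHC, truth).

    See the module docstring for the sampling scheme and draw order.
    Identical ``params`` (including ``seed``) reproduce the cohort exactly.
    """
    if params is None:
        params = CohortParams()
    params.validate()
    n = params.n_samples
    if n < 2:
        raise ParameterError(f"n_samples must be at least 2, got {n}")
    rng = np.random.default_rng(params.seed)
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    prev = np.array([params.subtype_prevalence.get(s, 0.0) for s in SUBTYPES])
    subtype_idx = rng.choice(len(SUBTYPES), size=n, p=prev)
    subtype = np.array(SUBTYPES, dtype=object)[subtype_idx]

    er_mu = np.array([params.er_activity_means[s] for s in subtype], dtype=float)
    er_act = rng.normal(er_mu, params.er_activity_sd)

    is_mapo = subtype == "mApo"
    gata3_high = np.zeros(n, dtype=bool)
    gata3_high[is_mapo] = rng.random(int(is_mapo.sum())) < params.gata3_high_mapo_fraction
    g3_mu = np.array([params.gata3_activity_means[s] for s in subtype], dtype=float)
    g3_mu[gata3_high] = params.mapo_gata3_high_mean
    g3_act = rng.normal(g3_mu, params.gata3_activity_sd)

    gene_names = sorted(params.gene_models)
    expr = np.empty((len(gene_names), n))
    pgr_dropped = np.zeros(n, dtype=bool)
    drives = {}
    for gi, g in enumerate(gene_names):
        gm = params.gene_models[g]
        drive = _gene_drive(gm, er_act, g3_act)
        noise = rng.normal(0.0, gm.noise_sd, size=n)
        vals = drive + noise
        if gm.dropout_prob:
            p_drop = np.array([gm.dropout_prob.get(s, 0.0) for s in subtype])
            drop = rng.random(n) < p_drop
            if drop.any():
                vals[drop] = gm.baseline + rng.normal(0.0, gm.noise_sd, size=int(drop.sum()))
            if g == "PGR":
                pgr_dropped = drop
        expr[gi] = vals
        drives[g] = drive

    true_er = drives["ESR1"] > _global_midpoint(params, params.gene_models["ESR1"]) \
        if "ESR1" in drives else np.zeros(n, dtype=bool)
    true_pr = drives["PGR"] > _global_midpoint(params, params.gene_models["PGR"]) \
        if "PGR" in drives else np.zeros(n, dtype=bool)

    flip_er = rng.random(n) < params.status_flip_prob_er
    flip_pr = rng.random(n) < params.status_flip_prob_pr
    er_status = np.where(true_er ^ flip_er, POSITIVE, NEGATIVE)
    pr_status = np.where(true_pr ^ flip_pr, POSITIVE, NEGATIVE)
    p_her2 = np.array([params.her2_positive_frac.get(s, 0.0) for s in subtype])
    her2_status = np.where(rng.random(n) < p_her2, POSITIVE, NEGATIVE)

    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_names, columns=sample_ids)
    )
    clinical = ClinicalTable(pd.DataFrame(
        {
            "er_status": er_status,
            "pr_status": pr_status,
            "her2_status": her2_status,
            "subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = pd.DataFrame(
        {
            "subtype": subtype,
            "er_activity": er_act,
            "gata3_activity": g3_act,
            "gata3_high_component": gata3_high,
            "true_er_class": true_er,
            "true_pr_class": true_pr,
            "pgr_dropped": pgr_dropped,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = SyntheticCohort(
        expression=expression, clinical=clinical, ihc=None, truth=truth, params=params,
    )
    cohort.ihc = generate_ihc_scores(cohort)
    lum_frac = float(np.isin(subtype, LUMINAL_SUBTYPES).mean())
    log.info("generated cohort: n=%d, luminal fraction %.3f, seed=%d",
             n, lum_frac, params.seed)
    return cohort


@dataclass
class ScoreCalibration:
    """Monotone map from log2 expression to IHC (proportion, intensity).

    A clipped linear ramp over [lo, hi]: proportion = clip((x−lo)/(hi−lo)),
    intensity = 3·clip(...). Expression at or below ``lo`` therefore maps
    exactly to (0, 0) and at or above ``hi`` to (1, 3). Gaussian noise with
    the given sds is added before clipping.
    """

    lo: float
    hi: float
    proportion_noise_sd: float = 0.05
    intensity_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ParameterError("calibration requires hi > lo")
        if self.proportion_noise_sd < 0 or self.intensity_noise_sd < 0:
            raise ParameterError("calibration noise sds must be non-negative")


def default_calibration(values: np.ndarray) -> ScoreCalibration:
    """Ramp over the central 80% of the observed expression range."""
    lo, hi = float(np.min(values)), float(np.max(values))
    span = hi - lo
    if span <= 0:
        raise ParameterError("cannot calibrate a constant expression vector")
    return ScoreCalibration(lo=lo + 0.1 * span, hi=hi - 0.1 * span)


def generate_ihc_scores(
    cohort: SyntheticCohort,
    markers: Mapping[str, str] | None = None,
    calibration: Mapping[str, ScoreCalibration] | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
) -> IHCTable:
    """Simulate per-core TMA staining summaries from the cohort's expression.

    Each tumor gets ``n_replicates`` cores per marker (TMA triplicates by
    default); proportion positive and intensity are monotone noisy ramps of
    the mapped gene's expression, clipped to [0, 1] and [0, 3].
    """
    if markers is None:
        markers = {
            m: g for m, g in DEFAULT_MARKER_GENES.items()
            if g in cohort.expression.data.index
        }
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if seed is None:
        seed = (cohort.params.seed + 1) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    sample_ids = cohort.expression.sample_ids
    rows = []
    for marker in sorted(markers):
        gene = markers[marker]
        x = cohort.expression.gene(gene)  # raises KeyError for absent genes
        cal = (calibration or {}).get(marker) or default_calibration(x)
        ramp = (x - cal.lo) / (cal.hi - cal.lo)
        for rep in range(1, n_replicates + 1):
            p_noise = (rng.normal(0.0, cal.proportion_noise_sd, size=len(x))
                       if cal.proportion_noise_sd > 0 else 0.0)
            i_noise = (rng.normal(0.0, cal.intensity_noise_sd, size=len(x))
                       if cal.intensity_noise_sd > 0 else 0.0)
            prop = np.clip(ramp + p_noise, 0.0, 1.0)
            inten = np.clip(3.0 * ramp + i_noise, 0.0, 3.0)
            for sid, p, i in zip(sample_ids, prop, inten):
                rows.append((sid, marker, p, i, f"core{rep}"))
    df = pd.DataFrame(
        rows,
        columns=["tumor_id", "marker", "proportion_positive", "intensity", "replicate_id"],
    )
    return IHCTable(df)
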
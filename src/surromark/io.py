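"""Tabular I/O for expression, clinical and IHC tables.

All interchange is TSV: UTF-8, '.' decimal separator, mandatory header row,
optional leading comment lines starting with ``#`` (used for provenance
headers on result tables). Three table types are supported:

* expression — ``gene_id<TAB>sample1<TAB>sample2...``, log2 expression values;
* clinical — ``sample_id, er_status, pr_status, her2_status, subtype``;
* IHC — ``tumor_id, marker, proportion_positive, intensity, replicate_id``.

Clinical status tokens are normalised case-insensitively to the ternary
{positive, negative, unknown} through a configurable map; unknown statuses
are retained here and excluded from concordance denominators downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, RangeError, StructuralError, TableParseError

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
STATUS_VALUES = (POSITIVE, NEGATIVE, UNKNOWN)

#: Default token → ternary status map (keys matched lower-case, stripped).
DEFAULT_STATUS_TOKENS: Mapping[str, str] = {
    "positive": POSITIVE,
    "pos": POSITIVE,
    "+": POSITIVE,
    "1": POSITIVE,
    "negative": NEGATIVE,
    "neg": NEGATIVE,
    "-": NEGATIVE,
    "0": NEGATIVE,
    "": UNKNOWN,
    "na": UNKNOWN,
    "nan": UNKNOWN,
    "none": UNKNOWN,
    "unknown": UNKNOWN,
}

CLINICAL_STATUS_COLUMNS = ("er_status", "pr_status", "her2_status")
IHC_COLUMNS = ("tumor_id", "marker", "proportion_positive", "intensity")


def _duplicates(values) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2 expression values.

    Backed by a float DataFrame whose index holds gene identifiers and whose
    columns hold sample identifiers. Identifiers must be unique and every
    value finite; construction validates both.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_genes = _duplicates(df.index)
        dup_samples = _duplicates(df.columns)
        if dup_genes or dup_samples:
            raise StructuralError(
                f"duplicate identifiers: genes={dup_genes}, samples={dup_samples}"
            )
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TableParseError("expression matrix contains non-numeric values")
        if values.size and not np.isfinite(values).all():
            raise StructuralError("expression matrix contains non-finite values")
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector for one gene, in sample order."""
        if gene_id not in self.data.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.data.loc[gene_id].to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Per-sample ternary ER/PR/HER2 calls plus an optional subtype label."""

    data: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        df = self.data
        dup = _duplicates(df.index)
        if dup:
            raise StructuralError(f"duplicate sample ids: {dup}")
        for col in CLINICAL_STATUS_COLUMNS:
            if col not in df.columns:
                df[col] = UNKNOWN
            bad = sorted(set(df[col]) - set(STATUS_VALUES))
            if bad:
                raise TableParseError(
                    f"column {col!r} has unmapped status values {bad}"
                )
        if "subtype" not in df.columns:
            df["subtype"] = None
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def status(self, column: str, sample_ids=None) -> np.ndarray:
        """Ternary status vector for one marker column, in the given order."""
        if column not in self.data.columns:
            raise KeyError(f"no clinical column {column!r}")
        series = self.data[column]
        if sample_ids is not None:
            series = series.reindex(sample_ids)
            if series.isna().any():
                missing = list(series.index[series.isna()])
                raise StructuralError(f"samples absent from clinical table: {missing}")
        return series.to_numpy()

    def subtypes(self, sample_ids=None) -> np.ndarray:
        series = self.data["subtype"]
        if sample_ids is not None:
            series = series.reindex(sample_ids)
        return series.to_numpy()


@dataclass
class IHCTable:
    """Per-core immunostaining summaries: proportion positive and intensity.

    ``proportion_positive`` lies in [0, 1] and ``intensity`` in [0, 3]
    (QuPath-style mean staining intensity). Replicate TMA cores are kept as
    separate rows distinguished by ``replicate_id``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in IHC_COLUMNS if c not in df.columns]
        if missing:
            raise StructuralError(f"IHC table missing columns {missing}")
        if "replicate_id" not in df.columns:
            df["replicate_id"] = ""
        df["replicate_id"] = df["replicate_id"].fillna("").astype(str)
        for col, lo, hi in (("proportion_positive", 0.0, 1.0), ("intensity", 0.0, 3.0)):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(df.index[vals.isna()][0])
                raise TableParseError(f"non-numeric {col} at row {row}")
            out = (vals < lo) | (vals > hi)
            if out.any():
                row = int(df.index[out][0])
                raise RangeError(
                    f"{col}={vals[out].iloc[0]} outside [{lo}, {hi}] at row {row} "
                    f"(tumor {df.loc[row, 'tumor_id']!r}, marker {df.loc[row, 'marker']!r})"
                )
            df[col] = vals.astype(float)
        key = df[["tumor_id", "marker", "replicate_id"]]
        dup_mask = key.duplicated()
        if dup_mask.any():
            first = key[dup_mask].iloc[0]
            raise StructuralError(
                "duplicate (tumor_id, marker, replicate_id): "
                f"{tuple(first)}"
            )
        self.data = df

    @property
    def tumor_ids(self) -> list[str]:
        return list(pd.unique(self.data["tumor_id"]))

    @property
    def markers(self) -> list[str]:
        return list(pd.unique(self.data["marker"]))


# ---------------------------------------------------------------------------
# Readers


def read_expression(path, on_missing: str = "drop_row") -> ExpressionMatrix:
    """Load a genes × samples expression TSV.

    Parameters
    ----------
    path : path-like
        TSV whose first column holds gene ids and remaining columns samples.
    on_missing : {"drop_row", "reject"}
        Policy for rows containing missing cells: drop them (logging the
        count) or raise. Non-numeric cells are always an error under
        ``reject`` and are treated as missing under ``drop_row``.
    """
    if on_missing not in ("drop_row", "reject"):
        raise ParameterError(
            f"on_missing must be 'drop_row' or 'reject', got {on_missing!r}"
        )
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#", dtype=str)
    raw.index = raw.index.astype(str)
    dup_genes = _duplicates(raw.index)
    dup_samples = _duplicates(raw.columns)
    if dup_genes or dup_samples:
        raise StructuralError(
            f"duplicate identifiers in {path}: genes={dup_genes}, samples={dup_samples}"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    originally_missing = raw.isna() | raw.apply(lambda s: s.str.strip() == "")
    unparsable = numeric.isna() & ~originally_missing
    if on_missing == "reject":
        bad = numeric.isna()
        if bad.to_numpy().any():
            gi, si = np.argwhere(bad.to_numpy())[0]
            raise TableParseError(
                f"missing or non-numeric cell at gene {raw.index[gi]!r}, "
                f"sample {raw.columns[si]!r}"
            )
    elif unparsable.to_numpy().any():
        gi, si = np.argwhere(unparsable.to_numpy())[0]
        log.warning(
            "treating non-numeric cell at gene %r, sample %r as missing",
            raw.index[gi], raw.columns[si],
        )
    incomplete = numeric.isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        log.info("dropping %d incomplete gene rows: %s",
                 n_dropped, list(numeric.index[incomplete])[:10])
        numeric = numeric.loc[~incomplete]
    matrix = ExpressionMatrix(numeric)
    log.info("read expression matrix: %d genes x %d samples (%d rows dropped)",
             matrix.n_genes, matrix.n_samples, n_dropped)
    return matrix


def normalize_status(token, token_map: Mapping[str, str] | None = None) -> str:
    """Map one raw status token to {positive, negative, unknown}."""
    table = DEFAULT_STATUS_TOKENS if token_map is None else token_map
    if token is None or (isinstance(token, float) and np.isnan(token)):
        key = ""
    else:
        key = str(token).strip().lower()
    if key not in table:
        raise TableParseError(f"unmapped clinical status token {str(token)!r}")
    return table[key]


def read_clinical(path, token_map: Mapping[str, str] | None = None) -> ClinicalTable:
    """Load a clinical annotation TSV keyed by ``sample_id``.

    Status columns are normalised through ``token_map`` (default
    :data:`DEFAULT_STATUS_TOKENS`); an unmapped token raises
    :class:`TableParseError` quoting it.
    """
    df = pd.read_csv(path, sep="\t", header=0, comment="#", dtype=str,
                     keep_default_na=False)
    if "sample_id" not in df.columns:
        raise StructuralError("clinical table must have a 'sample_id' column")
    status_cols = [c for c in CLINICAL_STATUS_COLUMNS if c in df.columns]
    if not status_cols:
        raise StructuralError(
            f"clinical table needs at least one of {CLINICAL_STATUS_COLUMNS}"
        )
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    for col in status_cols:
        df[col] = [normalize_status(t, token_map) for t in df[col]]
        n_unknown = int((df[col] == UNKNOWN).sum())
        if n_unknown:
            log.info("clinical column %s: %d unknown statuses", col, n_unknown)
        if n_unknown == len(df):
            log.warning("clinical column %s is entirely unknown", col)
    table = ClinicalTable(df)
    log.info("read clinical table: %d samples", len(df))
    return table


def read_ihc(path) -> IHCTable:
    """Load a per-core IHC score TSV (tumor, marker, proportion, intensity)."""
    df = pd.read_csv(path, sep="\t", header=0, comment="#", dtype=str,
                     keep_default_na=False)
    table = IHCTable(df)
    log.info("read IHC table: %d rows, %d tumors, markers=%s",
             len(table.data), len(table.tumor_ids), table.markers)
    return table


# ---------------------------------------------------------------------------
# Writers


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_expression(matrix: ExpressionMatrix, path, header_comment: str | None = None) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    _write_tsv(df, path, header_comment, index=True)


def write_clinical(table: ClinicalTable, path, header_comment: str | None = None) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    _write_tsv(df, path, header_comment, index=True)


def write_ihc(table: IHCTable, path, header_comment: str | None = None) -> None:
    _write_tsv(table.data, path, header_comment, index=False)
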
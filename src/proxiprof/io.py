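"""Readers and writers for protein-group quantification tables and
compartment annotation tables.

Two tab-separated dialects are supported for protein groups:

``generic``
    The package's own schema: columns ``group_id``, ``gene_name``,
    ``unique_peptides``, ``intensity_experimental``, ``intensity_control``,
    ``ratio``, ``is_reverse``, ``is_contaminant``.

``maxquant``
    A subset of the MaxQuant ``proteinGroups.txt`` dialect: ``Majority
    protein IDs``, ``Gene names``, ``Razor + unique peptides`` (or ``Unique
    peptides``), ``Ratio H/L``, ``Intensity H``, ``Intensity L``,
    ``Reverse``, ``Potential contaminant``.  Flag columns use ``+``.

Both are normalized into one in-memory model: a :class:`pandas.DataFrame`
with the generic columns above, one row per protein group.  ``ratio`` is the
experimental/control (+/− catalyst) intensity ratio; an empty cell means the
control channel gave no evidence for that protein in that replicate.

Annotation tables map an identifier to mitochondrial status, annotation
source, sub-mitochondrial location (``matrix*`` / IMS / MOM / unassigned)
and a mitochondria-associated-ER-membrane (MAM) flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RowParseError, TableFormatError

logger = logging.getLogger(__name__)

#: Canonical protein-group column order (the generic dialect).
PROTEIN_GROUP_COLUMNS = [
    "group_id",
    "gene_name",
    "unique_peptides",
    "intensity_experimental",
    "intensity_control",
    "ratio",
    "is_reverse",
    "is_contaminant",
]

_MAXQUANT_MAP = {
    "Majority protein IDs": "group_id",
    "Gene names": "gene_name",
    "Ratio H/L": "ratio",
    "Intensity H": "intensity_experimental",
    "Intensity L": "intensity_control",
    "Reverse": "is_reverse",
    "Potential contaminant": "is_contaminant",
}

VALID_SUBMITO = ("matrix_star", "IMS", "MOM", "unassigned")
VALID_SOURCES = ("MitoCarta", "UniProt", "both", "none")

_TRUE_TOKENS = {"+", "true", "1", "yes"}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUE_TOKENS


def _parse_positive_float(value, column: str, row_index: int) -> float:
    """Parse a ratio/intensity cell; empty -> NaN (absent)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip()
    if text == "" or text.lower() in ("nan", "na"):
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise RowParseError(
            f"non-numeric value {text!r} in column {column!r} at data row "
            f"{row_index}",
            row_index,
        ) from None


def read_protein_groups(path, dialect: str = "generic") -> pd.DataFrame:
    """Read one replicate's protein-group table into the generic model.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with one header row.
    dialect : {"generic", "maxquant"}

    Returns
    -------
    DataFrame with :data:`PROTEIN_GROUP_COLUMNS`.  No row is ever silently
    dropped: every input row either appears in the output or raises a
    :class:`RowParseError` carrying its index.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "maxquant":
        missing = [
            c
            for c in _MAXQUANT_MAP
            if c not in raw.columns and c != "Ratio H/L"
        ]
        if "Razor + unique peptides" in raw.columns:
            peptide_col = "Razor + unique peptides"
        elif "Unique peptides" in raw.columns:
            peptide_col = "Unique peptides"
        else:
            missing.append("Razor + unique peptides")
            peptide_col = None
        if "Ratio H/L" not in raw.columns:
            missing.append("Ratio H/L")
        if missing:
            raise TableFormatError(
                "missing mandatory column(s): " + ", ".join(sorted(missing))
            )
        frame = raw.rename(columns=_MAXQUANT_MAP)
        frame["unique_peptides"] = raw[peptide_col]
    elif dialect == "generic":
        missing = [c for c in PROTEIN_GROUP_COLUMNS if c not in raw.columns]
        if missing:
            raise TableFormatError(
                "missing mandatory column(s): " + ", ".join(missing)
            )
        frame = raw
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out = pd.DataFrame(index=frame.index)
    out["group_id"] = frame["group_id"].astype(str)
    if (out["group_id"].str.strip() == "").any():
        bad = int(np.flatnonzero(out["group_id"].str.strip() == "")[0])
        raise RowParseError(f"empty group_id at data row {bad}", bad)
    out["gene_name"] = frame["gene_name"].astype(str)
    peptides = [
        _parse_positive_float(v, "unique_peptides", i)
        for i, v in enumerate(frame["unique_peptides"])
    ]
    out["unique_peptides"] = [
        0 if not np.isfinite(p) else int(p) for p in peptides
    ]
    for col in ("intensity_experimental", "intensity_control", "ratio"):
        out[col] = [
            _parse_positive_float(v, col, i)
            for i, v in enumerate(frame[col])
        ]
    ratios = out["ratio"].to_numpy(float)
    nonpos = np.flatnonzero(np.isfinite(ratios) & (ratios <= 0))
    if nonpos.size:
        bad = int(nonpos[0])
        raise RowParseError(
            f"ratio must be strictly positive; got {ratios[bad]} at data "
            f"row {bad}",
            bad,
        )
    out["is_reverse"] = [_parse_flag(v) for v in frame["is_reverse"]]
    out["is_contaminant"] = [_parse_flag(v) for v in frame["is_contaminant"]]
    return out[PROTEIN_GROUP_COLUMNS]


@dataclass(frozen=True)
class AnnotationRecord:
    identifier: str
    is_mito: bool = False
    source: str = "none"
    submito: str = "unassigned"
    is_mam: bool = False


_NONE_RECORD = AnnotationRecord("")


class AnnotationDB:
    """Identifier -> compartment annotation lookup.

    Matching against protein groups uses the first accession of a
    semicolon-joined majority-ID list, falling back to the gene name.
    Unknown identifiers resolve to the none-annotation default.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        cols = ["identifier", "is_mito", "source", "submito", "is_mam"]
        if frame is None:
            frame = pd.DataFrame(columns=cols)
        self.frame = frame[cols].reset_index(drop=True)
        self._records: dict[str, AnnotationRecord] = {
            row.identifier: AnnotationRecord(
                row.identifier,
                bool(row.is_mito),
                row.source,
                row.submito,
                bool(row.is_mam),
            )
            for row in self.frame.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._records

    def lookup(self, identifier: str) -> AnnotationRecord:
        return self._records.get(identifier, _NONE_RECORD)

    def match(self, group_id: str, gene_name: str = "") -> AnnotationRecord:
        """Resolve a protein group: first accession, then gene-name fallback."""
        first = str(group_id).split(";")[0].strip()
        rec = self._records.get(first)
        if rec is not None:
            return rec
        gene = str(gene_name).split(";")[0].strip()
        if gene:
            rec = self._records.get(gene)
            if rec is not None:
                return rec
        return _NONE_RECORD

    def n_submito(self, submito: str) -> int:
        """Number of annotated proteins in one sub-mitochondrial class."""
        return int((self.frame["submito"] == submito).sum())


def read_annotations(path) -> AnnotationDB:
    """Read a tab-separated annotation table.

    Mandatory column: ``identifier``.  Optional columns ``is_mito``,
    ``source``, ``submito``, ``is_mam`` default to false / ``none`` /
    ``unassigned`` / false.  A submito other than ``unassigned`` forces
    ``is_mito`` true (the location implies the compartment).  Duplicate
    identifiers: last one wins, with a logged warning.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "identifier" not in raw.columns:
        raise TableFormatError("missing mandatory column(s): identifier")
    n = len(raw)
    is_mito = (
        [_parse_flag(v) for v in raw["is_mito"]]
        if "is_mito" in raw.columns
        else [False] * n
    )
    source = (
        [str(v).strip() or "none" for v in raw["source"]]
        if "source" in raw.columns
        else ["none"] * n
    )
    submito = (
        [str(v).strip() or "unassigned" for v in raw["submito"]]
        if "submito" in raw.columns
        else ["unassigned"] * n
    )
    is_mam = (
        [_parse_flag(v) for v in raw["is_mam"]]
        if "is_mam" in raw.columns
        else [False] * n
    )
    # Accept the display form "matrix*" used in figure-style tables.
    submito = ["matrix_star" if s == "matrix*" else s for s in submito]
    for s in submito:
        if s not in VALID_SUBMITO:
            raise TableFormatError(
                f"unknown submito token {s!r}; valid tokens: "
                + ", ".join(VALID_SUBMITO)
            )
    for s in source:
        if s not in VALID_SOURCES:
            raise TableFormatError(
                f"unknown source token {s!r}; valid tokens: "
                + ", ".join(VALID_SOURCES)
            )
    is_mito = [m or s != "unassigned" for m, s in zip(is_mito, submito)]
    frame = pd.DataFrame(
        {
            "identifier": raw["identifier"].astype(str),
            "is_mito": is_mito,
            "source": source,
            "submito": submito,
            "is_mam": is_mam,
        }
    )
    dups = frame["identifier"].duplicated(keep="last")
    if dups.any():
        logger.warning(
            "%d duplicate identifier(s) in %s; keeping last occurrence",
            int(dups.sum()),
            path,
        )
        frame = frame[~dups]
    return AnnotationDB(frame)


def annotations_to_frame(ann: AnnotationDB) -> pd.DataFrame:
    return ann.frame.copy()


def write_table(records: pd.DataFrame, path) -> None:
    """Write any tabular pipeline output as deterministic TSV.

    UTF-8, one header row, rows sorted by ``group_id``/``identifier``
    (stable) when such a column exists, absent values as empty cells.
    """
    if records is None:
        raise ValueError("records must not be None")
    frame = records.copy()
    for key in ("group_id", "identifier", "protein"):
        if key in frame.columns:
            frame = frame.sort_values(key, kind="stable")
            break
    frame.to_csv(path, sep="\t", index=False, na_rep="", encoding="utf-8")
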
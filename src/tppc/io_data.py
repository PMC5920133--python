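"""Reading, validating and aligning matched omics tables.

The package operates on two numeric layers measured over the same samples: a
transcript matrix (genes x samples) and a metabolite matrix (metabolites x
samples). Tables are delimited text (TSV/CSV) with a header row of sample
identifiers and variable identifiers in the first column. Variables are rows
by convention; ``orientation="samples"`` transposes on read for tables stored
the other way around.

Values are assumed to be pre-normalised upstream (platform-specific
normalisation is out of scope here); this module only parses, validates and
aligns them.
"""

from __future__ import annotations

import csv
import enum
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    IdentifierError,
    InsufficientOverlapError,
    TableFormatError,
    TableParseError,
    TPPCError,
)

__all__ = [
    "Layer",
    "OmicsMatrix",
    "MatchedDataset",
    "read_omics_table",
    "align_samples",
    "write_pair_table",
    "read_pair_table",
    "PAIR_TABLE_COLUMNS",
]

#: Strings treated as missing values on read.
NA_STRINGS = frozenset({"", "NA", "NaN", "nan", "N/A", "null", "NULL"})


class Layer(str, enum.Enum):
    """Which omics layer a matrix belongs to."""

    TRANSCRIPT = "transcript"
    METABOLITE = "metabolite"


@dataclass(frozen=True)
class OmicsMatrix:
    """A variables x samples numeric matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_variables, n_samples)``; all entries finite.
    variable_ids, sample_ids
        Unique identifiers for rows and columns respectively.
    layer
        Either :attr:`Layer.TRANSCRIPT` or :attr:`Layer.METABOLITE`.
    """

    values: np.ndarray
    variable_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    layer: Layer

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_ids", tuple(map(str, self.variable_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "layer", Layer(self.layer))
        if values.ndim != 2:
            raise TableFormatError("values must be a 2-D matrix")
        if values.shape != (len(self.variable_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.variable_ids)} variables x {len(self.sample_ids)} samples"
            )
        for name, ids in (("variable", self.variable_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise IdentifierError(f"duplicate {name} identifier(s): {sorted(dupes)}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise TableParseError(
                f"non-finite value at variable {self.variable_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame with variable ids as index, sample ids as columns."""
        return pd.DataFrame(
            self.values, index=list(self.variable_ids), columns=list(self.sample_ids)
        )

    def subset_samples(self, sample_ids: list[str] | tuple[str, ...]) -> "OmicsMatrix":
        """Restrict the matrix to ``sample_ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - guarded by callers
            raise IdentifierError(f"unknown sample identifier {exc.args[0]!r}") from exc
        return OmicsMatrix(
            values=self.values[:, idx],
            variable_ids=self.variable_ids,
            sample_ids=tuple(sample_ids),
            layer=self.layer,
        )


@dataclass(frozen=True)
class MatchedDataset:
    """Transcript and metabolite layers aligned to an identical sample order."""

    transcripts: OmicsMatrix
    metabolites: OmicsMatrix

    def __post_init__(self) -> None:
        if self.transcripts.sample_ids != self.metabolites.sample_ids:
            raise InsufficientOverlapError(
                "transcript and metabolite layers are not aligned on the same "
                "samples; use align_samples() first"
            )

    @property
    def n_samples(self) -> int:
        return self.transcripts.n_samples


def _duplicates(items) -> set:
    seen, dupes = set(), set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes


def _infer_delimiter(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_omics_table(
    path: str | os.PathLike,
    layer: Layer | str,
    delimiter: str | None = None,
    orientation: str = "variables",
    na_policy: str = "reject",
) -> OmicsMatrix:
    """Parse a delimited omics table.

    Parameters
    ----------
    path
        Input file; first row sample identifiers, first column variable ids.
    layer
        ``"transcript"`` or ``"metabolite"``.
    delimiter
        Field separator; inferred from the extension when ``None``
        (``.csv`` -> comma, otherwise tab).
    orientation
        ``"variables"`` (rows are variables, the default) or ``"samples"``
        (table is transposed on read).
    na_policy
        ``"reject"`` raises on any missing cell; ``"drop_variable"`` removes
        every variable with at least one missing entry.
    """
    if orientation not in ("variables", "samples"):
        raise TPPCError(f"unknown orientation {orientation!r}")
    if na_policy not in ("reject", "drop_variable"):
        raise TPPCError(f"unknown na_policy {na_policy!r}")
    sep = delimiter if delimiter is not None else _infer_delimiter(path)

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows[0]) < 2:
        raise TableFormatError(f"{path}: no parseable header row")
    header = [c.strip() for c in rows[0]]
    sample_ids = header[1:]
    width = len(rows[0])
    body = [r for r in rows[1:] if r and not all(c.strip() == "" for c in r)]
    for k, row in enumerate(body, start=2):
        if len(row) != width:
            raise TableFormatError(
                f"{path}: ragged row at line {k} ({len(row)} fields, expected {width})"
            )
    variable_ids = [r[0].strip() for r in body]

    dupes = _duplicates(sample_ids)
    if dupes:
        raise IdentifierError(f"{path}: duplicate sample identifier(s): {sorted(dupes)}")
    dupes = _duplicates(variable_ids)
    if dupes:
        raise IdentifierError(f"{path}: duplicate variable identifier(s): {sorted(dupes)}")

    values = np.empty((len(body), len(sample_ids)), dtype=float)
    missing_rows: set[int] = set()
    for i, row in enumerate(body):
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in NA_STRINGS:
                if na_policy == "reject":
                    raise TableParseError(
                        f"{path}: missing value at variable {variable_ids[i]!r}, "
                        f"sample {sample_ids[j]!r} (na_policy=reject)"
                    )
                missing_rows.add(i)
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise TableParseError(
                    f"{path}: non-numeric cell {cell!r} at variable "
                    f"{variable_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    if missing_rows:
        keep = [i for i in range(len(body)) if i not in missing_rows]
        values = values[keep]
        variable_ids = [variable_ids[i] for i in keep]

    matrix = OmicsMatrix(values, tuple(variable_ids), tuple(sample_ids), Layer(layer))
    if orientation == "samples":
        matrix = OmicsMatrix(
            matrix.values.T, matrix.sample_ids, matrix.variable_ids, matrix.layer
        )
    return matrix


def align_samples(
    transcripts: OmicsMatrix,
    metabolites: OmicsMatrix,
    min_samples: int = 5,
) -> MatchedDataset:
    """Restrict both layers to their shared samples.

    The shared samples keep the transcript layer's column order, which makes
    alignment deterministic and idempotent.
    """
    met_set = set(metabolites.sample_ids)
    shared = [s for s in transcripts.sample_ids if s in met_set]
    if len(shared) < min_samples:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared sample(s) between layers; "
            f"need at least {min_samples}"
        )
    return MatchedDataset(
        transcripts=transcripts.subset_samples(shared),
        metabolites=metabolites.subset_samples(shared),
    )


#: Column schema of the pair table written by :func:`write_pair_table`.
PAIR_TABLE_COLUMNS = (
    "metabolite_1",
    "metabolite_2",
    "pearson_r",
    "partial_r",
    "p_pearson",
    "p_partial",
    "p_diff",
    "q_pearson",
    "q_partial",
    "q_diff",
    "category",
)


def write_pair_table(pairs, path: str | os.PathLike) -> None:
    """Write per-pair statistics as a TSV with a fixed column schema.

    Rows are sorted lexicographically by ``(metabolite_1, metabolite_2)`` and
    floats are printed with 6 significant digits, so output is deterministic.
    """
    records = [
        {
            "metabolite_1": p.metabolite_1,
            "metabolite_2": p.metabolite_2,
            "pearson_r": p.r_pearson,
            "partial_r": p.r_partial,
            "p_pearson": p.p_pearson,
            "p_partial": p.p_partial,
            "p_diff": p.p_diff,
            "q_pearson": p.q_pearson,
            "q_partial": p.q_partial,
            "q_diff": p.q_diff,
            "category": p.category,
        }
        for p in pairs
    ]
    frame = pd.DataFrame.from_records(records, columns=list(PAIR_TABLE_COLUMNS))
    if len(frame):
        frame = frame.sort_values(["metabolite_1", "metabolite_2"], kind="mergesort")
    tmp = f"{path}.tmp"
    frame.to_csv(tmp, sep="\t", index=False, float_format="%.6g")
    os.replace(tmp, path)


def read_pair_table(path: str | os.PathLike):
    """Read a pair table written by :func:`write_pair_table`."""
    from .categorization import PairStatistics  # local import avoids a cycle

    frame = pd.read_csv(path, sep="\t", dtype={"metabolite_1": str, "metabolite_2": str})
    missing = set(PAIR_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise TableFormatError(f"{path}: missing pair-table column(s): {sorted(missing)}")
    return [
        PairStatistics(
            metabolite_1=row.metabolite_1,
            metabolite_2=row.metabolite_2,
            r_pearson=row.pearson_r,
            r_partial=row.partial_r,
            p_pearson=row.p_pearson,
            p_partial=row.p_partial,
            p_diff=row.p_diff,
            q_pearson=row.q_pearson,
            q_partial=row.q_partial,
            q_diff=row.q_diff,
            category=row.category,
        )
        for row in frame.itertuples(index=False)
    ]
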
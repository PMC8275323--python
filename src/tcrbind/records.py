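"""Binding records and tabular IO.

The atom of every dataset here is one (epitope, TCR, label) triple: a short
antigenic peptide, a TCR beta-chain sequence (CDR3 loop or full variable
region) and a binary flag for whether binding was observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .encoding import AA_ALPHABET

logger = logging.getLogger(__name__)

__all__ = ["BindingRecord", "load_records", "records_to_frame", "write_records",
           "ConfigurationError", "DataError"]


class ConfigurationError(ValueError):
    """Bad user-supplied configuration (missing columns, invalid modes...)."""


class DataError(ValueError):
    """Input data unusable (no valid rows, empty result after filtering...)."""


_VALID_CHARS = set(AA_ALPHABET)


@dataclass(frozen=True)
class BindingRecord:
    """One epitope-TCR pair with a binary binding label.

    ``tcr_id`` identifies the receptor for split bookkeeping; it defaults to
    the sequence itself, so identical sequences collapse to one identity and
    cross-fold leakage is judged at the sequence level.
    """

    epitope_seq: str
    tcr_seq: str
    label: int
    tcr_id: str = field(default="")

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.tcr_id:
            object.__setattr__(self, "tcr_id", self.tcr_seq)


def _sequence_ok(seq: str) -> bool:
    return bool(seq) and all(c in _VALID_CHARS for c in seq)


def load_records(path, fmt: str = "csv",
                 column_map: dict | None = None) -> list[BindingRecord]:
    """Read binding records from a delimited table.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.
    fmt : {"csv", "tsv"}
    column_map : dict, optional
        Maps the canonical names ``epitope``, ``tcr``, ``label`` (and
        optionally ``tcr_id``) to the column names present in the file.

    Rows with empty or out-of-alphabet sequences are dropped; the count of
    rejected rows is logged.
    """
    if fmt not in ("csv", "tsv"):
        raise ConfigurationError(f"unknown format {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)

    cmap = {"epitope": "epitope", "tcr": "tcr", "label": "label"}
    cmap.update(column_map or {})
    for canonical in ("epitope", "tcr", "label"):
        if cmap[canonical] not in df.columns:
            raise ConfigurationError(
                f"column {cmap[canonical]!r} (for {canonical!r}) not in "
                f"{list(df.columns)}")

    id_col = cmap.get("tcr_id")
    records, rejected = [], 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(row)
        epi = str(row.get(cmap["epitope"], "") or "").strip().upper()
        tcr = str(row.get(cmap["tcr"], "") or "").strip().upper()
        if not (_sequence_ok(epi) and _sequence_ok(tcr)):
            rejected += 1
            continue
        label = int(float(row[cmap["label"]]))
        tcr_id = str(row[id_col]) if id_col and id_col in row else ""
        records.append(BindingRecord(epi, tcr, label, tcr_id))
    if rejected:
        logger.warning("rejected %d rows with empty/non-alphabet sequences", rejected)
    if not records:
        raise DataError(f"no valid rows in {path}")
    return records


def records_to_frame(records: list[BindingRecord],
                     folds: dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "epitope": [r.epitope_seq for r in records],
        "tcr": [r.tcr_seq for r in records],
        "label": [r.label for r in records],
    })
    if folds is not None:
        df["fold"] = [folds[i] for i in range(len(records))]
    return df


def write_records(records: list[BindingRecord], path,
                  folds: dict | None = None) -> None:
    records_to_frame(records, folds).to_csv(path, index=False)
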
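"""Sequence and annotation I/O plus the shared record model.

Transcript/EST sequences arrive as nucleotide FASTA; functional
annotation arrives as two flat TSV files: a sequence-id → GO-term table
and a GO → GO-Slim mapping. Everything downstream consumes the
:class:`SequenceRecord` and :class:`AnnotationTable` containers defined
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC nucleotide alphabet (uppercase); anything else is a format error.
IUPAC_CODES = set("ACGTNRYSWKMBDHV")
UNAMBIGUOUS = set("ACGT")


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header, empty record, duplicate id)."""


class TableFormatError(ValueError):
    """Malformed TSV annotation input."""


@dataclass
class SequenceRecord:
    """One annotated nucleotide sequence.

    Parameters
    ----------
    id : str
        Unique identifier (first whitespace-delimited FASTA header token).
    sequence : str
        DNA over the IUPAC alphabet, stored uppercase.
    description : str
        Remainder of the FASTA header after the id.
    go_terms : set of str
        Possibly empty set of GO identifiers ("GO:NNNNNNN").
    """

    id: str
    sequence: str
    description: str = ""
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = "".join(self.sequence.split()).upper()
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        self.sequence = seq

    @property
    def is_annotated(self) -> bool:
        return len(self.go_terms) > 0


@dataclass
class AnnotationTable:
    """Sequence→GO rows plus a GO→GO-Slim mapping.

    ``rows`` holds unique ``(sequence_id, go_id)`` pairs;
    ``slim_map`` maps GO ids to broad GO-Slim terms. GO ids without a
    slim mapping stay in ``rows`` but are reported as unbinned.
    """

    rows: pd.DataFrame  # columns: sequence_id, go_id
    slim_map: dict[str, str]

    def go_terms_for(self, sequence_id: str) -> set[str]:
        sub = self.rows.loc[self.rows["sequence_id"] == sequence_id, "go_id"]
        return set(sub)

    def slim_terms_for(self, sequence_id: str) -> set[str]:
        return {
            self.slim_map[g]
            for g in self.go_terms_for(sequence_id)
            if g in self.slim_map
        }


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a nucleotide FASTA file into :class:`SequenceRecord` objects.

    Order is preserved; sequences are uppercased. Duplicate ids and
    structurally broken files raise :class:`FastaFormatError`.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def _validate_fasta_structure(path: Path) -> None:
    """Reject sequence-before-header and empty records with line numbers."""
    header_line: int | None = None
    have_seq = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not have_seq:
                    raise FastaFormatError(
                        f"{path}:{header_line}: record has no sequence"
                    )
                if not stripped[1:].strip():
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                have_seq = False
            else:
                if header_line is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                have_seq = True
    if header_line is not None and not have_seq:
        raise FastaFormatError(f"{path}:{header_line}: record has no sequence")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _read_two_col_tsv(path: Path, what: str) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns "
                    f"in {what}, got {len(parts)}"
                )
            out.append((parts[0].strip(), parts[1].strip()))
    return out


def read_annotations(go_path: str | Path, slim_path: str | Path,
                     valid_ids: set[str] | None = None) -> AnnotationTable:
    """Load sequence→GO rows and the GO→slim map.

    Rows referencing a sequence absent from ``valid_ids`` (when given)
    are dropped with a warning; duplicate ``(sequence_id, go_id)`` pairs
    are collapsed.
    """
    go_rows = _read_two_col_tsv(Path(go_path), "GO annotation table")
    slim_rows = _read_two_col_tsv(Path(slim_path), "GO-Slim map")
    slim_map = dict(slim_rows)

    df = pd.DataFrame(go_rows, columns=["sequence_id", "go_id"])
    before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < before:
        logger.info("dropped %d duplicate annotation rows", before - len(df))
    if valid_ids is not None:
        orphan = ~df["sequence_id"].isin(valid_ids)
        if orphan.any():
            logger.warning(
                "dropping %d annotation rows for unknown sequence ids (e.g. %s)",
                int(orphan.sum()), df.loc[orphan, "sequence_id"].iloc[0],
            )
            df = df.loc[~orphan].reset_index(drop=True)
    unmapped = ~df["go_id"].isin(slim_map)
    if unmapped.any():
        logger.info("%d annotation rows have no GO-Slim mapping (kept, unbinned)",
                    int(unmapped.sum()))
    return AnnotationTable(rows=df, slim_map=slim_map)


def attach_annotations(records: list[SequenceRecord],
                       table: AnnotationTable) -> None:
    """Populate ``record.go_terms`` in place from an annotation table."""
    by_seq = table.rows.groupby("sequence_id")["go_id"].agg(set).to_dict()
    for rec in records:
        rec.go_terms = set(by_seq.get(rec.id, set()))


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: header first, UTF-8, '.' decimals, NA
    for missing values."""
    rows.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], encoding="utf-8")
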
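"""Sequence and metadata I/O, and the column filter producing the analysis matrix.

All downstream statistics (site classification, p-distances, dating) operate on
an :class:`Alignment` whose columns have been filtered down to unambiguous
A/C/G/T by :func:`filter_columns` — the "complete deletion" convention, under
which a column is discarded if *any* sequence carries a gap (``-``), a missing
symbol (``?``) or an IUPAC ambiguity code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ACGT = frozenset("ACGT")
GAP = "-"
MISSING = "?"
#: IUPAC nucleotide ambiguity codes (everything sequence-like that is not ACGT)
AMBIGUOUS = frozenset("RYSWKMBDHVNU")

_VALID = ACGT | AMBIGUOUS | {GAP, MISSING}


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its specimen metadata.

    ``locality_code``, ``lot`` and ``group`` are empty strings when unknown;
    ``group`` holds the lineage label used for supervised partitioning.
    """

    id: str
    residues: str
    taxon: str = ""
    locality_code: str = ""
    lot: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues.upper()) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length sequences."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment requires at least one record")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ColumnFilterReport:
    """Audit of which columns :func:`filter_columns` removed and why.

    ``excluded_reasons`` maps 0-based column index to one of
    ``{"gap", "missing", "ambiguous"}`` (first matching reason, priority
    gap > missing > ambiguous).
    """

    n_input_columns: int
    n_excluded: int
    n_retained: int
    excluded_reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input_columns != self.n_excluded + self.n_retained:
            raise ValueError("inconsistent filter report totals")
        if len(self.excluded_reasons) != self.n_excluded:
            raise ValueError("every excluded column needs exactly one reason")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input_columns": self.n_input_columns,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "excluded_reasons": {str(k): v for k, v in self.excluded_reasons.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into records; the first whitespace-delimited header token is the id.

    Residues are upper-cased and record order is preserved. Raises
    :class:`FastaParseError` on sequence data before any header and
    ``ValueError`` on duplicate ids.
    """
    path = Path(path)
    # Bio.SeqIO silently tolerates leading junk; pre-scan for a hard error
    # naming the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA (round-trip stable)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> Alignment:
    """Read a pre-aligned FASTA (no aligner is invoked here)."""
    return Alignment(tuple(read_fasta(path)))


def _column_reason(column: str) -> str | None:
    """First matching exclusion reason for a column, priority gap > missing > ambiguous."""
    if GAP in column:
        return "gap"
    if MISSING in column:
        return "missing"
    if set(column) - ACGT:
        return "ambiguous"
    return None


def filter_columns(
    aln: Alignment, exclude: frozenset[str] | set[str] = frozenset({"gap", "missing", "ambiguous"})
) -> tuple[Alignment, ColumnFilterReport]:
    """Drop every column containing an excluded symbol class (complete deletion).

    ``exclude`` is a subset of ``{"gap", "missing", "ambiguous"}``. Retained
    columns keep their original order. Raises ``ValueError`` if nothing is
    retained — an empty alignment is never returned.
    """
    exclude = frozenset(exclude)
    bad = exclude - {"gap", "missing", "ambiguous"}
    if bad:
        raise ValueError(f"unknown exclusion tags: {sorted(bad)}")

    keep: list[int] = []
    reasons: dict[int, str] = {}
    for j in range(aln.length):
        reason = _column_reason(aln.column(j))
        if reason is not None and reason in exclude:
            reasons[j] = reason
        else:
            keep.append(j)
    if not keep:
        raise ValueError("column filter removed every column of the alignment")

    new_records = tuple(
        SequenceRecord(
            id=r.id,
            residues="".join(r.residues[j] for j in keep),
            taxon=r.taxon,
            locality_code=r.locality_code,
            lot=r.lot,
            group=r.group,
        )
        for r in aln.records
    )
    report = ColumnFilterReport(
        n_input_columns=aln.length,
        n_excluded=len(reasons),
        n_retained=len(keep),
        excluded_reasons=reasons,
    )
    return Alignment(new_records), report


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a delimited specimen table keyed by ``id``.

    Accepts CSV or TSV (sniffed from the header line). Recognised columns
    besides the mandatory ``id``: ``taxon``, ``locality_code``, ``lot``,
    ``group``; missing optional fields become empty strings.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata table requires an 'id' column")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        rid = row["id"].strip()
        if not rid:
            raise ValueError(f"{path}: empty id in metadata row")
        if rid in out:
            raise ValueError(f"{path}: duplicate metadata id {rid!r}")
        out[rid] = {
            key: row.get(key, "").strip()
            for key in ("taxon", "locality_code", "lot", "group")
        }
    return out


def join_metadata(
    records: Iterable[SequenceRecord], meta: Mapping[str, Mapping[str, str]]
) -> list[SequenceRecord]:
    """Attach metadata fields to sequence records by id.

    Every sequence id must appear in the table; unmatched ids raise a
    ``ValueError`` listing them all.
    """
    records = list(records)
    unmatched = [r.id for r in records if r.id not in meta]
    if unmatched:
        raise ValueError(f"sequence ids missing from metadata table: {unmatched}")
    return [
        SequenceRecord(
            id=r.id,
            residues=r.residues,
            taxon=meta[r.id].get("taxon", ""),
            locality_code=meta[r.id].get("locality_code", ""),
            lot=meta[r.id].get("lot", ""),
            group=meta[r.id].get("group", ""),
        )
        for r in records
    ]
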
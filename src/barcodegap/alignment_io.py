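"""Reading, validating and writing barcode alignments and specimen metadata.

A dataset is a pre-aligned DNA FASTA file (one row per specimen, equal
lengths) plus a tab-separated specimen table mapping each sequence id to a
species label and an ingroup/outgroup role.  ``bind`` joins the two into a
:class:`LabeledAlignment`, the substrate of every downstream analysis.

Character conventions
---------------------
Sequences are upper-cased on input and ``U`` is mapped to ``T``.  The gap
``-``, ``N``, ``?`` and the ten IUPAC ambiguity codes are all treated as
*missing* for every downstream computation: pairwise deletion skips them,
and the diagnostic-site detector never lets an ambiguous call support or
contradict a diagnosis.  Site indices are 1-based alignment columns in all
user-facing output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    BindingError,
    DuplicateIdError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("barcodegap")

#: Canonical nucleotide states.
BASES = ("A", "C", "G", "T")

#: Symbols treated as missing under pairwise deletion (gap, hard missing,
#: and all IUPAC ambiguity codes).
MISSING_SYMBOLS = frozenset("-N?RYSWKMBDHV")

ALLOWED_CHARS = frozenset(BASES) | MISSING_SYMBOLS

ROLES = ("ingroup", "outgroup")
SEXES = ("male", "female", "unknown")

#: Integer encoding used by the numeric engines: A,C,G,T -> 0..3, missing -> 255.
MISSING_CODE = np.uint8(255)

_CODE_LUT = np.full(256, MISSING_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen: sequence id, species label, tree role, optional metadata."""

    seq_id: str
    species: str
    role: str
    accession: str | None = None
    sex: str | None = None
    locality: str | None = None

    def __post_init__(self):
        if not self.seq_id:
            raise ValidationError("seq_id must be non-empty")
        if not self.species:
            raise ValidationError(f"record {self.seq_id!r}: species must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(
                f"record {self.seq_id!r}: role {self.role!r} not allowed; "
                f"allowed values: {', '.join(ROLES)}"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(
                f"record {self.seq_id!r}: sex {self.sex!r} not allowed; "
                f"allowed values: {', '.join(SEXES)}"
            )


@dataclass(frozen=True)
class RawAlignment:
    """Parsed FASTA alignment before metadata binding: ids + character matrix."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # (n, L) of single characters, dtype '<U1'

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, seq_id: str) -> str:
        i = self.ids.index(seq_id)
        return "".join(self.matrix[i])


@dataclass(frozen=True)
class LabeledAlignment:
    """Aligned sequences joined to specimen records, ordered by metadata order."""

    records: tuple[SpecimenRecord, ...]
    matrix: np.ndarray  # (n, L) single characters, dtype '<U1'
    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.records)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != n:
            raise AlignmentShapeError(
                f"matrix shape {self.matrix.shape} does not match {n} records"
            )
        if self.L < 1:
            raise AlignmentShapeError("alignment must have at least one site")
        codes = _CODE_LUT[self.matrix.view(np.uint32).astype(np.uint32) & 0xFF]
        object.__setattr__(self, "_codes", np.ascontiguousarray(codes))
        empty = (self._codes == MISSING_CODE).all(axis=1)
        if empty.any():
            bad = self.records[int(np.flatnonzero(empty)[0])].seq_id
            raise ValidationError(f"sequence {bad!r} has no non-missing characters")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.seq_id for r in self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def L(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def codes(self) -> np.ndarray:
        """(n, L) uint8 encoding: A,C,G,T -> 0..3; any missing symbol -> 255."""
        return self._codes

    def sequence(self, seq_id: str) -> str:
        i = self.ids.index(seq_id)
        return "".join(self.matrix[i])

    def species_of(self) -> dict[str, str]:
        return {r.seq_id: r.species for r in self.records}

    def species_labels(self, role: str | None = None) -> tuple[str, ...]:
        """Distinct species labels in record order, optionally filtered by role."""
        seen: dict[str, None] = {}
        for r in self.records:
            if role is None or r.role == role:
                seen.setdefault(r.species, None)
        return tuple(seen)

    def subset(self, seq_ids: Iterable[str]) -> "LabeledAlignment":
        keep = set(seq_ids)
        idx = [i for i, r in enumerate(self.records) if r.seq_id in keep]
        return LabeledAlignment(
            records=tuple(self.records[i] for i in idx),
            matrix=self.matrix[idx].copy(),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _normalize_row(seq_id: str, seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALLOWED_CHARS
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise AlphabetError(
            f"sequence {seq_id!r}: illegal character {s[pos]!r} at site {pos + 1}"
        )
    return s


def read_fasta_alignment(path: str | Path) -> RawAlignment:
    """Read an aligned FASTA file into a :class:`RawAlignment`.

    Rows are upper-cased, ``U`` becomes ``T``, input order is preserved.
    Raises :class:`AlignmentShapeError` on unequal row lengths,
    :class:`AlphabetError` on characters outside DNA + missing symbols, and
    :class:`DuplicateIdError` on repeated headers.
    """
    path = Path(path)
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise ValidationError(f"{path}: no FASTA records found")
    ids: list[str] = []
    rows: list[str] = []
    for rec in seqs:
        if rec.id in ids:
            raise DuplicateIdError(f"{path}: duplicate header {rec.id!r}")
        ids.append(rec.id)
        rows.append(_normalize_row(rec.id, str(rec.seq)))
    L = len(rows[0])
    for seq_id, row in zip(ids, rows):
        if len(row) != L:
            raise AlignmentShapeError(
                f"{path}: record {seq_id!r} has length {len(row)}, expected {L}"
            )
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return RawAlignment(ids=tuple(ids), matrix=matrix)


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen metadata TSV (header; columns seq_id, species, role).

    Optional recognized columns: accession, sex, locality.  Other columns are
    ignored with a logged note.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"seq_id", "species", "role"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    optional = {"accession", "sex", "locality"}
    extra = set(df.columns) - required - optional
    if extra:
        logger.info("metadata %s: ignoring unknown column(s): %s",
                    path, ", ".join(sorted(extra)))
    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                seq_id=row["seq_id"],
                species=row["species"],
                role=row["role"],
                accession=row.get("accession") or None,
                sex=row.get("sex") or None,
                locality=row.get("locality") or None,
            )
        )
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise DuplicateIdError(f"{path}: duplicate seq_id {dup!r}")
    return records


def bind(
    raw: RawAlignment,
    records: Sequence[SpecimenRecord],
    strict: bool = True,
) -> LabeledAlignment:
    """Join a raw alignment to specimen records.

    Strict mode requires the two id sets to be equal; lenient mode keeps the
    intersection (dropped ids are logged).  Output rows follow metadata order.
    """
    fasta_ids = set(raw.ids)
    meta_ids = set(r.seq_id for r in records)
    only_fasta = fasta_ids - meta_ids
    only_meta = meta_ids - fasta_ids
    if strict and (only_fasta or only_meta):
        parts = []
        if only_fasta:
            parts.append(f"in FASTA only: {', '.join(sorted(only_fasta))}")
        if only_meta:
            parts.append(f"in metadata only: {', '.join(sorted(only_meta))}")
        raise BindingError("id sets differ (strict binding): " + "; ".join(parts))
    if only_fasta or only_meta:
        logger.warning(
            "lenient binding dropped %d FASTA-only and %d metadata-only id(s)",
            len(only_fasta), len(only_meta),
        )
    keep = [r for r in records if r.seq_id in fasta_ids]
    if not keep:
        raise BindingError("no ids shared between FASTA and metadata")
    pos = {sid: i for i, sid in enumerate(raw.ids)}
    matrix = raw.matrix[[pos[r.seq_id] for r in keep]].copy()
    return LabeledAlignment(records=tuple(keep), matrix=matrix)


def load_labeled_alignment(
    fasta_path: str | Path, metadata_path: str | Path, strict: bool = True
) -> LabeledAlignment:
    """Convenience: read FASTA + metadata and bind them."""
    return bind(read_fasta_alignment(fasta_path), read_metadata(metadata_path), strict)


def write_fasta_alignment(aln: LabeledAlignment | RawAlignment, path: str | Path) -> None:
    """Write an alignment back to (unwrapped) FASTA, preserving order."""
    if isinstance(aln, LabeledAlignment):
        ids = aln.ids
    else:
        ids = aln.ids
    recs = [
        SeqRecord(Seq("".join(aln.matrix[i])), id=ids[i], description="")
        for i in range(len(ids))
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    """Write specimen records as the metadata TSV consumed by read_metadata."""
    df = pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in records],
            "species": [r.species for r in records],
            "role": [r.role for r in records],
            "accession": [r.accession or "" for r in records],
            "sex": [r.sex or "" for r in records],
            "locality": [r.locality or "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
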
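"""Core sequence containers: :class:`SequenceRecord` and :class:`Alignment`.

All internal coordinates are 0-based half-open; user-facing reports convert
to 1-based inclusive residue numbering (the convention used for structures
such as GLIC).  ``'-'`` and ``'.'`` are both gap characters; readers
normalise ``'.'`` to ``'-'`` and upcase residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import AlignmentFormatError, ContractError

GAP = "-"
GAP_CHARS = frozenset("-.")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues permitted in a record: the 20 amino acids, unknown 'X', gap
ALPHABET = AMINO_ACIDS | {"X", GAP}


def normalize_residues(residues: str) -> str:
    """Upcase and map '.' gaps to '-'."""
    return residues.upper().replace(".", GAP)


@dataclass
class SequenceRecord:
    """One identified protein sequence (possibly gapped, in aligned context)."""

    id: str
    residues: str
    description: str = ""
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ContractError("sequence id must be non-empty")
        if not self.residues:
            raise ContractError(f"record {self.id!r}: residues must be non-empty")
        self.residues = normalize_residues(self.residues)
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


def ungap(residues: str) -> tuple[str, dict[int, int]]:
    """Strip gaps, returning the gapless string and a map from gapless
    position to original column index.

    ``len(gapless) + n_gaps == len(residues)`` always holds.
    """
    residues = normalize_residues(residues)
    chars = []
    index_map: dict[int, int] = {}
    for col, ch in enumerate(residues):
        if ch != GAP:
            index_map[len(chars)] = col
            chars.append(ch)
    return "".join(chars), index_map


class Alignment:
    """An ordered collection of equal-length gapped sequence records."""

    def __init__(self, records: list[SequenceRecord]):
        if not records:
            raise AlignmentFormatError("alignment must contain at least one record")
        width = len(records[0].residues)
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise AlignmentFormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.residues) != width:
                raise AlignmentFormatError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {width}"
                )
        if width < 1:
            raise AlignmentFormatError("alignment must have at least one column")
        self.records: list[SequenceRecord] = list(records)
        self.n_columns: int = width
        self._index = {rec.id: i for i, rec in enumerate(self.records)}
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def get(self, seq_id: str) -> SequenceRecord:
        try:
            return self.records[self._index[seq_id]]
        except KeyError:
            raise KeyError(f"no record with id {seq_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def matrix(self) -> np.ndarray:
        """Character matrix view (n_records x n_columns, dtype '<U1'), cached."""
        if self._matrix is None:
            self._matrix = np.array(
                [list(rec.residues) for rec in self.records], dtype="<U1"
            )
        return self._matrix

    def column(self, i: int) -> str:
        if not 0 <= i < self.n_columns:
            raise ContractError(f"column {i} out of range [0, {self.n_columns})")
        return "".join(self.matrix()[:, i])

    def take_columns(self, columns: "np.ndarray | list[int]") -> "Alignment":
        """New alignment keeping the given columns, row order unchanged."""
        mat = self.matrix()[:, list(columns)]
        recs = [
            SequenceRecord(
                rec.id, "".join(row), rec.description, rec.taxon_label
            )
            for rec, row in zip(self.records, mat)
        ]
        return Alignment(recs)

    def subset(self, ids: list[str]) -> "Alignment":
        return Alignment([self.get(i) for i in ids])
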
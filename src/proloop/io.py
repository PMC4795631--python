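"""Readers and writers: FASTA (aligned/unaligned, optionally inside a ZIP),
Stockholm (read-only), and the TSV taxon table.

Parsing of the standard formats is delegated to Biopython; this module only
adds the domain containers, gap normalisation and error reporting.
"""

from __future__ import annotations

import io as _io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import AlignIO, SeqIO

from .errors import AlignmentFormatError, EmptyInputError, TaxonTableError
from .records import Alignment, SequenceRecord

Source = Union[str, Path, IO]

#: the closed set of taxonomic groups used throughout the pipeline
GROUPS = ("metazoa", "bacteria", "archaea", "protist")


def _open_text(source: Source) -> IO:
    """Return a text handle; transparently unwraps a ZIP holding one FASTA."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if zipfile.is_zipfile(path):
            zf = zipfile.ZipFile(path)
            members = [n for n in zf.namelist() if not n.endswith("/")]
            if len(members) != 1:
                raise AlignmentFormatError(
                    f"ZIP {path} must contain exactly one file, found {len(members)}"
                )
            return _io.TextIOWrapper(zf.open(members[0]), encoding="utf-8")
        return open(path, "rt", encoding="utf-8")
    return source


def parse_sequences(source: Source, format: str = "fasta") -> list[SequenceRecord]:
    """Read (possibly unaligned) sequences, preserving input order."""
    if format not in ("fasta", "stockholm"):
        raise AlignmentFormatError(f"unsupported format {format!r}")
    handle = _open_text(source)
    records = []
    for rec in SeqIO.parse(handle, format):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    if not records:
        raise EmptyInputError("no sequence records found in input")
    return records


def parse_alignment(source: Source, format: str = "fasta") -> Alignment:
    """Read an alignment; ragged rows raise naming the offending record."""
    return Alignment(parse_sequences(source, format=format))


def write_fasta(records: Iterable[SequenceRecord] | Alignment, dest: Source, width: int = 60) -> None:
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt", encoding="utf-8")
        close = True
    else:
        handle = dest
    try:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}" if not rec.description.startswith(rec.id)
                else rec.description
            )
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


@dataclass
class TaxonTable:
    """Maps sequence id -> (species, group), with group drawn from GROUPS.

    Lookup tolerates both bare-id and id-plus-annotation FASTA headers: an
    exact match is tried first, then the token before the first whitespace
    or '|' separator.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, seq_id: str, species: str, group: str) -> None:
        group = group.strip().lower()
        if group not in GROUPS:
            raise TaxonTableError(
                f"id {seq_id!r}: group {group!r} not in {GROUPS}"
            )
        if not species:
            raise TaxonTableError(f"id {seq_id!r}: species must be non-empty")
        self.entries[seq_id] = (species, group)

    def lookup(self, seq_id: str) -> tuple[str, str] | None:
        hit = self.entries.get(seq_id)
        if hit is not None:
            return hit
        token = seq_id.split()[0].split("|")[0]
        return self.entries.get(token)

    def group_of(self, seq_id: str) -> str | None:
        hit = self.lookup(seq_id)
        return hit[1] if hit else None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return self.lookup(seq_id) is not None


def read_taxon_table(source: Source) -> TaxonTable:
    """TSV with columns id, species, group; '#' lines are comments."""
    handle = _open_text(source)
    table = TaxonTable()
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise TaxonTableError(f"line {lineno}: expected 3 tab-separated columns")
        table.add(parts[0], parts[1], parts[2])
    if not table.entries:
        raise EmptyInputError("taxon table is empty")
    return table


def write_taxon_table(table: TaxonTable, dest: Source) -> None:
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt", encoding="utf-8")
        close = True
    else:
        handle = dest
    try:
        handle.write("#id\tspecies\tgroup\n")
        for seq_id, (species, group) in table.entries.items():
            handle.write(f"{seq_id}\t{species}\t{group}\n")
    finally:
        if close:
            handle.close()
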
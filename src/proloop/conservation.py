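"""Gap-excluding conservation statistics, the conserved-cluster report, the
50%-gap column filter, and TM-block alignment QC.

The conservation measure excludes gaps (to prevent bias due to fragmentary
sequences) and 'X' (unknown residues should not dilute the statistic): a
column's conservation is the modal residue's frequency among its non-gap,
non-X symbols.  The report layer rounds percentages half-away-from-zero to
integers; everything internal stays unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ProloopError
from .records import GAP, Alignment, ungap

#: "similar residues" for the group-conservation rule: aromatics, acidics,
#: basics, aliphatics, and the helix-breaking P/G pair; configurable.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("FYW"),
    frozenset("DE"),
    frozenset("RK"),
    frozenset("ILVM"),
    frozenset("PG"),
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ConservationRow:
    """Per-column statistics in the style of a conserved-residue table."""

    column: int
    top_residue: str | None
    conservation_pct: float  # of non-gap, non-X residues
    gap_pct: float  # over all rows
    substitutions: list[tuple[str, float]] = field(default_factory=list)
    group_conservation_pct: float = 0.0
    reference_positions: dict[str, int | None] = field(default_factory=dict)

    @property
    def all_gap(self) -> bool:
        return self.top_residue is None


def _column_counts(col: np.ndarray) -> tuple[dict[str, int], int, int]:
    """(residue counts excluding gap/X, n_gaps, n_rows)."""
    values, counts = np.unique(col, return_counts=True)
    table = dict(zip(values.tolist(), counts.tolist()))
    n_gap = table.pop(GAP, 0)
    table.pop("X", None)
    return table, n_gap, int(col.size)


def column_conservation(
    aln: Alignment,
    column: int,
    similarity_groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS,
    substitution_min_pct: float = 2.0,
) -> ConservationRow:
    """Gap-excluding conservation of one alignment column.

    An all-gap column yields a row with ``top_residue=None`` (flagged, not
    an error).
    """
    if not 0 <= column < aln.n_columns:
        raise ContractError(f"column {column} out of range")
    col = aln.matrix()[:, column]
    table, n_gap, n_rows = _column_counts(col)
    gap_pct = 100.0 * n_gap / n_rows
    total = sum(table.values())
    if total == 0:
        return ConservationRow(column, None, 0.0, gap_pct)
    # deterministic tie-break: higher count first, then alphabetical
    top = min(table, key=lambda r: (-table[r], r))
    freqs = {r: 100.0 * c / total for r, c in table.items()}
    conservation = freqs[top]
    group = next((g for g in similarity_groups if top in g), frozenset({top}))
    group_pct = sum(freqs[r] for r in freqs if r in group or r == top)
    subs = sorted(
        ((r, p) for r, p in freqs.items() if r != top and p >= substitution_min_pct),
        key=lambda item: (-item[1], item[0]),
    )
    return ConservationRow(column, top, conservation, gap_pct, subs, group_pct)


def _reference_positions(
    aln: Alignment, refs: list[tuple[str, int]], column: int
) -> dict[str, int | None]:
    """1-based residue number of each reference at a column (None if gapped)."""
    out: dict[str, int | None] = {}
    for ref_id, offset in refs:
        row = aln.get(ref_id).residues
        if row[column] == GAP:
            out[ref_id] = None
            continue
        _, index_map = ungap(row)
        inv = {c: p for p, c in index_map.items()}
        out[ref_id] = inv[column] + 1 + offset
    return out


def conserved_positions_report(
    aln: Alignment,
    refs: list[tuple[str, int]] | None = None,
    threshold_pct: float = 80.0,
    gap_max_pct: float = 2.0,
    similarity_groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS,
) -> list[ConservationRow]:
    """Columns with gap content below ``gap_max_pct`` whose conservation —
    single-residue or summed over a similarity group — is strictly above
    ``threshold_pct``, annotated with reference residue numbers.
    """
    refs = refs or []
    for ref_id, _ in refs:
        if ref_id not in aln:
            raise ProloopError(f"reference {ref_id!r} not in alignment")
    rows = []
    for column in range(aln.n_columns):
        row = column_conservation(aln, column, similarity_groups)
        if row.all_gap or row.gap_pct >= gap_max_pct:
            continue
        if row.conservation_pct > threshold_pct or row.group_conservation_pct > threshold_pct:
            row.reference_positions = _reference_positions(aln, refs, column)
            rows.append(row)
    return rows


def gap_fractions(aln: Alignment) -> np.ndarray:
    """Per-column gap fraction in [0, 1] ('X' counts as a residue)."""
    return (aln.matrix() == GAP).mean(axis=0)


def filter_gappy_columns(aln: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Drop columns with *more than* ``max_gap_fraction`` gaps.

    Columns at exactly the threshold are retained; row order and ids are
    unchanged; the operation is idempotent.
    """
    keep = np.flatnonzero(gap_fractions(aln) <= max_gap_fraction)
    if keep.size == 0:
        raise ProloopError(
            f"no columns with gap fraction <= {max_gap_fraction}; "
            "raise the threshold"
        )
    return aln.take_columns(keep)


@dataclass
class BlockGapStat:
    start: int
    end: int  # half-open
    fraction_with_gap: float
    passed: bool


def tm_block_gap_qc(
    aln: Alignment,
    block_columns: list[tuple[int, int]],
    max_fraction: float = 0.1,
) -> tuple[list[BlockGapStat], bool]:
    """Per-block fraction of sequences with >= 1 gap inside the block.

    Key secondary-structure elements (the TM helices) should be indel-free
    in a trustworthy alignment; each block passes when its fraction is at or
    below ``max_fraction``.
    """
    mat = aln.matrix()
    stats = []
    for start, end in block_columns:
        if not (0 <= start < end <= aln.n_columns):
            raise ContractError(f"block ({start}, {end}) outside alignment")
        frac = float((mat[:, start:end] == GAP).any(axis=1).mean())
        stats.append(BlockGapStat(start, end, frac, frac <= max_fraction))
    return stats, all(s.passed for s in stats)
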
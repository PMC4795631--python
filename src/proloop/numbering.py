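"""Universal prime numbering for transmembrane helices M1, M2 (+M2M3 loop)
and M3.

Residues are numbered from the cytoplasmic toward the extracellular side.
For M1 the C-terminal aromatic (GLIC W217) is 1' and primes *decrease* along
the sequence (pre-M1 Arg = 26', the M1-kink Pro = 14'); M2 keeps the classic
convention (0' at the conserved basic residue, primes increase, extension to
25' with labels above a configurable cut tagged M2M3); M3 starts at 29' (the
initial T/P/K: GLIC T253, Torpedo nAChR-alpha P272, GABA_A beta3 K279) and
primes decrease.  M4 is deliberately left unnumbered: it shows too little
conservation for a global scheme to be reliable.

Primes are assigned by counting each sequence's own ungapped residues from
the residue it carries in the anchor column — not by alignment column — so
indels in the M1M2 linker (common in prokaryotes and 5HT3) do not corrupt
M2 numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ContractError, ProloopError
from .records import GAP, Alignment, ungap

M1 = "M1"
M2 = "M2"
M2M3 = "M2M3"
M3 = "M3"

#: anchor name -> (helix, prime value at the anchor)
ANCHOR_PRIMES = {
    "m1_R26": (M1, 26),
    "m1_P14": (M1, 14),
    "m1_W1": (M1, 1),
    "m2_zero": (M2, 0),
    "m3_29": (M3, 29),
}

#: expected residue identities at each anchor (warnings only, never failures)
_EXPECTED = {
    "m1_R26": set("R"),
    "m1_P14": set("P"),
    "m1_W1": set("FWY"),
    "m2_zero": set("KR"),
    "m3_29": set("TPK"),
}

M1_SPAN = 26  # primes 26' down to 1'
M2_SPAN = 26  # primes 0' .. 25'
M3_SPAN = 29  # primes 29' down to 1'
DEFAULT_M2M3_CUT = 20  # M2 primes above this are tagged M2M3


@dataclass
class AnchorColumns:
    """Alignment column (0-based) of each named anchor."""

    columns: dict[str, int]
    provenance: str = "reference_row"
    m2m3_cut: int = DEFAULT_M2M3_CUT

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(ANCHOR_PRIMES)
        if unknown:
            raise ContractError(f"unknown anchor names: {sorted(unknown)}")
        ordered = [self.columns[k] for k in
                   ("m1_R26", "m1_P14", "m1_W1", "m2_zero", "m3_29")
                   if k in self.columns]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ContractError(
                f"anchor columns must be strictly increasing, got {self.columns}"
            )


@dataclass
class PrimeAnnotation:
    """Per-residue helix/prime labels plus per-sequence quality flags."""

    #: (sequence id, gapless 0-based position) -> (helix, prime)
    entries: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)
    #: sequence id -> helices whose anchor column was a gap in that row
    gapped_at_anchor: dict[str, set[str]] = field(default_factory=dict)
    #: sequences where same-helix anchors disagree (indel between anchors)
    indel_flags: set[str] = field(default_factory=set)

    def get(self, seq_id: str, pos: int) -> tuple[str, int] | None:
        return self.entries.get((seq_id, pos))

    def primes_for(self, seq_id: str, helix: str) -> dict[int, int]:
        """prime -> gapless position for one sequence and helix."""
        return {
            prime: pos
            for (sid, pos), (hx, prime) in self.entries.items()
            if sid == seq_id and hx == helix
        }


def locate_anchors(
    aln: Alignment,
    reference_id: str,
    reference_offsets: dict[str, int],
    m2m3_cut: int = DEFAULT_M2M3_CUT,
) -> AnchorColumns:
    """Map 1-based residue numbers of a reference row to alignment columns.

    E.g. GLIC with offsets {m1_R26: 192, m1_P14: 204, m1_W1: 217, m3_29: 253}.
    Residue-identity mismatches at anchors produce warnings, not failures.
    """
    if reference_id not in aln:
        raise ProloopError(f"reference {reference_id!r} not in alignment")
    row = aln.get(reference_id).residues
    gapless, index_map = ungap(row)
    if not gapless:
        raise ProloopError(f"reference {reference_id!r} is all gaps")
    columns: dict[str, int] = {}
    for anchor, resnum in reference_offsets.items():
        if anchor not in ANCHOR_PRIMES:
            raise ContractError(f"unknown anchor name {anchor!r}")
        pos = resnum - 1
        if not 0 <= pos < len(gapless):
            raise ProloopError(
                f"anchor {anchor}: residue {resnum} beyond reference length "
                f"{len(gapless)}"
            )
        if gapless[pos] not in _EXPECTED[anchor]:
            warnings.warn(
                f"anchor {anchor}: reference residue {gapless[pos]!r} at "
                f"{resnum} not in expected set {sorted(_EXPECTED[anchor])}",
                stacklevel=2,
            )
        columns[anchor] = index_map[pos]
    return AnchorColumns(columns, provenance="reference_row", m2m3_cut=m2m3_cut)


def _column_to_gapless(row: str) -> dict[int, int]:
    _, index_map = ungap(row)
    return {col: pos for pos, col in index_map.items()}


def assign_primes(aln: Alignment, anchors: AnchorColumns) -> PrimeAnnotation:
    """Assign helix primes per sequence by ungapped counting from anchors.

    A sequence gapped at an anchor column gets no annotation for that helix
    and a per-sequence flag.  No residue ever carries two annotations: a
    would-be collision is skipped and flagged as an indel anomaly.
    """
    ann = PrimeAnnotation()
    plan: list[tuple[str, str, int, int, int]] = []  # anchor, helix, prime0, step, span
    if "m1_R26" in anchors.columns:
        plan.append(("m1_R26", M1, 26, -1, M1_SPAN))
    elif "m1_W1" in anchors.columns:
        # fallback: count backwards from 1' (primes increase toward N-term)
        plan.append(("m1_W1", M1, 1, -1, M1_SPAN))
    if "m2_zero" in anchors.columns:
        plan.append(("m2_zero", M2, 0, +1, M2_SPAN))
    if "m3_29" in anchors.columns:
        plan.append(("m3_29", M3, 29, -1, M3_SPAN))

    for rec in aln:
        inv = _column_to_gapless(rec.residues)
        n = len(rec.ungapped())
        for anchor, helix, prime0, step, span in plan:
            col = anchors.columns[anchor]
            if rec.residues[col] == GAP:
                ann.gapped_at_anchor.setdefault(rec.id, set()).add(helix)
                continue
            gpos = inv[col]
            if anchor == "m1_W1":
                # walk toward the N-terminus from 1'
                positions = range(gpos, max(-1, gpos - span), -1)
                primes = range(1, 1 + span)
            else:
                positions = range(gpos, min(n, gpos + span))
                primes = (prime0 + step * d for d in range(span))
            for pos, prime in zip(positions, primes):
                if pos < 0 or pos >= n:
                    break
                label = helix
                if helix == M2 and prime > anchors.m2m3_cut:
                    label = M2M3
                key = (rec.id, pos)
                if key in ann.entries:
                    ann.indel_flags.add(rec.id)
                    continue
                ann.entries[key] = (label, prime)
        # self-consistency: secondary M1 anchors must land on their primes
        for anchor, expected_prime in (("m1_P14", 14), ("m1_W1", 1)):
            if anchor not in anchors.columns or "m1_R26" not in anchors.columns:
                continue
            col = anchors.columns[anchor]
            if rec.residues[col] == GAP:
                continue
            got = ann.entries.get((rec.id, inv[col]))
            if got != (M1, expected_prime):
                ann.indel_flags.add(rec.id)
    return ann


def extract_m2_triplet(row: str, m2_zero_col: int) -> str:
    """The -2'/-1'/0' residues of one aligned row, for selectivity calling.

    The 0' residue is the one in the anchor column; -1' and -2' are the two
    ungapped residues immediately preceding it.  Gaps (0' itself gapped, or
    fewer than two preceding residues) are reported as '-' so the caller's
    gapped-triplet path engages.
    """
    if not 0 <= m2_zero_col < len(row):
        raise ContractError("m2_zero column outside row")
    if row[m2_zero_col] == GAP:
        return "---"
    gapless, index_map = ungap(row)
    inv = {col: pos for pos, col in index_map.items()}
    gpos = inv[m2_zero_col]
    chars = [gapless[gpos - 2] if gpos >= 2 else "-",
             gapless[gpos - 1] if gpos >= 1 else "-",
             gapless[gpos]]
    return "".join(chars)
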
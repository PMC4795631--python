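"""Pro-loop motif detection, Cys-loop/Cys-less classification, and M2
ion-selectivity calls.

The [F/Y]PxD motif at the tip of the beta6-beta7 loop is the defining
signature of the pLGIC superfamily; the variant with a terminal E instead of
D (as in the Dirofilaria immitis channel) still counts as a Pro loop, and
only the flanking cysteines decide Cys-loop versus Cys-less status.  The M2
-2'/-1'/0' triplet carries the charge-selectivity signature: GE[K/R]
correlates with cation selectivity, A[R/K] with anion selectivity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ContractError

_CANONICAL = re.compile(r"[FY]P.D")
_ACIDIC_VARIANT = re.compile(r"[FY]P.E")

CYS_LOOP = "cys_loop"
CYS_LESS = "cys_less"
SINGLE_CYS = "single_cys"

CATIONIC = "cationic_type"
ANIONIC = "anionic_type"
UNDETERMINED = "undetermined"

#: default flanking-Cys search windows (residues before motif start /
#: after motif end), bracketing the known Cys-loop geometry: in GABA_A beta3
#: the cysteines sit ~8 residues before and ~6 after the motif.
DEFAULT_WINDOW_UP = (4, 14)
DEFAULT_WINDOW_DOWN = (3, 12)


@dataclass(frozen=True)
class MotifHit:
    """Leftmost Pro-loop match on a gapless sequence (0-based positions)."""

    start: int
    pattern: str  # one of FPxD, YPxD, FPxE, YPxE
    proline_pos: int
    is_acidic_variant: bool

    def __post_init__(self) -> None:
        if self.proline_pos != self.start + 1:
            raise ContractError("proline must be the second motif residue")

    @property
    def end(self) -> int:
        """Index of the last motif residue (the D/E)."""
        return self.start + 3


@dataclass(frozen=True)
class CysStatus:
    value: str  # cys_loop | cys_less | single_cys
    upstream_cys_pos: int | None = None
    downstream_cys_pos: int | None = None

    def __post_init__(self) -> None:
        both = self.upstream_cys_pos is not None and self.downstream_cys_pos is not None
        neither = self.upstream_cys_pos is None and self.downstream_cys_pos is None
        if self.value == CYS_LOOP and not both:
            raise ContractError("cys_loop requires both cysteine positions")
        if self.value == CYS_LESS and not neither:
            raise ContractError("cys_less requires no cysteine positions")


@dataclass(frozen=True)
class SelectivityCall:
    value: str  # cationic_type | anionic_type | undetermined
    basic_at_zero_prime: bool
    triplet: str
    gapped: bool = False


def detect_proloop(residues: str) -> MotifHit | None:
    """Find the leftmost [F/Y]PxD motif; fall back to the [F/Y]PxE variant.

    Positions are gapless and 0-based.  Absence is a valid result (None).
    """
    m = _CANONICAL.search(residues)
    if m is not None:
        pattern = f"{residues[m.start()]}PxD"
        return MotifHit(m.start(), pattern, m.start() + 1, is_acidic_variant=False)
    m = _ACIDIC_VARIANT.search(residues)
    if m is not None:
        pattern = f"{residues[m.start()]}PxE"
        return MotifHit(m.start(), pattern, m.start() + 1, is_acidic_variant=True)
    return None


def classify_cys_status(
    residues: str,
    hit: MotifHit,
    window_up: tuple[int, int] = DEFAULT_WINDOW_UP,
    window_down: tuple[int, int] = DEFAULT_WINDOW_DOWN,
) -> CysStatus:
    """Search for flanking cysteines around a Pro-loop hit.

    The upstream window is [start - up_max, start - up_min], the downstream
    window [end + down_min, end + down_max] (both inclusive, truncated at
    the sequence boundaries).  Both found -> cys_loop; neither -> cys_less;
    exactly one -> single_cys.
    """
    up_min, up_max = min(window_up), max(window_up)
    down_min, down_max = min(window_down), max(window_down)
    n = len(residues)

    def find_cys(lo: int, hi: int) -> int | None:
        lo, hi = max(0, lo), min(n - 1, hi)
        for i in range(lo, hi + 1):
            if residues[i] == "C":
                return i
        return None

    up = find_cys(hit.start - up_max, hit.start - up_min)
    down = find_cys(hit.end + down_min, hit.end + down_max)
    if up is not None and down is not None:
        return CysStatus(CYS_LOOP, up, down)
    if up is None and down is None:
        return CysStatus(CYS_LESS)
    return CysStatus(SINGLE_CYS, up, down)


def call_selectivity(triplet: str) -> SelectivityCall:
    """Classify the M2 -2'/-1'/0' triplet.

    -1'/0' = E then K/R -> cationic_type; -1'/0' = A then R/K ->
    anionic_type; anything else -> undetermined.  A gap anywhere in the
    triplet yields undetermined with the ``gapped`` flag set.
    """
    if len(triplet) != 3:
        raise ContractError(f"triplet must have length 3, got {triplet!r}")
    triplet = triplet.upper()
    if "-" in triplet or "." in triplet:
        return SelectivityCall(UNDETERMINED, False, triplet, gapped=True)
    basic = triplet[2] in "KR"
    if triplet[1] == "E" and basic:
        return SelectivityCall(CATIONIC, True, triplet)
    if triplet[1] == "A" and basic:
        return SelectivityCall(ANIONIC, True, triplet)
    return SelectivityCall(UNDETERMINED, basic, triplet)
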
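"""Candidate hit validation: the 2-of-3 decision rule combining externally
supplied reverse-search evidence, a membrane-topology criterion, and a
pairwise-alignment criterion, plus terminal trimming to the pLGIC domains.

The topology scorer is pluggable: any callable mapping a gapless sequence to
per-residue scores in [0, 1] can stand behind the fixed contract (threshold
0.2, minimum segment length, short-gap merging).  The built-in default is a
sliding-window Kyte-Doolittle hydropathy profile rescaled affinely per
sequence so the most hydrophobic window maps to 1 and the most hydrophilic
to 0.  The pore-facing helix M2 is less hydrophobic than M1/M3/M4 and is
not consistently detected, which is why the pLGIC layout check accepts
three or more segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import ContractError

DEFAULT_TM_THRESHOLD = 0.2
DEFAULT_MIN_TM_LEN = 15
DEFAULT_MERGE_GAP = 3
DEFAULT_WINDOW = 19
#: identity cutoff for the "aligns well with known pLGICs" criterion —
#: deliberately permissive, as pLGICs share <20% identity across kingdoms
DEFAULT_IDENTITY_CUTOFF = 0.15
DEFAULT_MIN_COVERAGE = 0.6


@dataclass(frozen=True)
class TMSegment:
    """A predicted transmembrane stretch (gapless, 0-based, half-open)."""

    start: int
    end: int
    mean_score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ContractError("TMSegment requires start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ValidationReport:
    """Outcome of the three validation criteria and the 2-of-3 decision."""

    reverse_search: bool | None
    topology: bool
    alignment: bool
    details: dict[str, str] = field(default_factory=dict)

    @property
    def n_satisfied(self) -> int:
        # an absent reverse search counts as unsatisfied, never satisfied
        return sum(1 for c in (self.reverse_search, self.topology, self.alignment) if c)

    @property
    def decision(self) -> bool:
        return self.n_satisfied >= 2


def hydropathy_scores(residues: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Normalized sliding-window hydropathy profile in [0, 1].

    Each residue receives the mean Kyte-Doolittle value of the window
    centred on it, rescaled so the most hydrophobic window is 1 and the most
    hydrophilic 0; window centres too close to an end take the nearest full
    window's value.  A flat profile maps to all zeros.
    """
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in residues])
    n = len(values)
    if n < window:
        return np.zeros(0)
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    scores = np.empty(n)
    scores[half : half + len(means)] = means
    scores[:half] = means[0]
    scores[half + len(means):] = means[-1]
    lo, hi = scores.min(), scores.max()
    if hi - lo < 1e-12:
        return np.zeros(n)
    return (scores - lo) / (hi - lo)


def predict_topology(
    residues: str,
    scorer: Callable[[str], np.ndarray] | None = None,
    threshold: float = DEFAULT_TM_THRESHOLD,
    min_len: int = DEFAULT_MIN_TM_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[TMSegment]:
    """Maximal runs of residues scoring >= threshold, merged across sub-
    threshold gaps of at most ``merge_gap`` residues, kept if >= min_len.
    """
    scorer = scorer or hydropathy_scores
    scores = np.asarray(scorer(residues), dtype=float)
    if scores.size == 0:
        warnings.warn("sequence shorter than scoring window; no topology", stacklevel=2)
        return []
    if scores.size != len(residues):
        raise ContractError("scorer must return one score per residue")
    if scores.min() < 0 or scores.max() > 1:
        raise ContractError("scorer must return values in [0, 1]")
    above = scores >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if runs and i - runs[-1][1] <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j
        else:
            i += 1
    return [
        TMSegment(a, b, float(scores[a:b].mean()))
        for a, b in runs
        if b - a >= min_len
    ]


def check_plgic_topology(
    segments: Sequence[TMSegment],
    seq_len: int,
    truncated: bool = False,
) -> tuple[bool, str]:
    """Is the predicted topology compatible with a pLGIC subunit?

    Requires (a) at least three TM segments (M2 may be missed), all within
    the C-terminal 60% of the sequence, and (b) an N-terminal segment-free
    stretch of >= 100 residues (the ECD).  ``truncated`` relaxes (b) for
    fragmentary candidates.
    """
    if seq_len <= 0:
        raise ContractError("seq_len must be positive")
    if len(segments) < 3:
        return False, f"only {len(segments)} TM segments (need >= 3)"
    cterm_start = 0.4 * seq_len
    if any(seg.start < cterm_start for seg in segments):
        return False, "TM segments extend into the N-terminal 40% (no ECD layout)"
    if not truncated:
        first_tm = min(seg.start for seg in segments)
        if first_tm < 100:
            return False, f"N-terminal segment-free stretch only {first_tm} residues"
    return True, f"{len(segments)} TM segments after an ECD-like N-terminus"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity_score(candidate: str, reference: str) -> float:
    """Fraction of identical aligned pairs over the global alignment length
    (BLOSUM62, affine gaps -11/-1)."""
    if not candidate or not reference:
        raise ContractError("both sequences must be non-empty")
    alignment = _make_aligner().align(candidate, reference)[0]
    row_a, row_b = alignment[0], alignment[1]
    identities = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
    return identities / len(row_a)


def alignment_criterion(
    candidate: str,
    references: Sequence[str],
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[bool, float]:
    """Does the candidate align well with any reference pLGIC?

    Satisfied when, for some reference, the global identity fraction reaches
    the cutoff and at least ``min_coverage`` of candidate residues are
    aligned to reference residues (not gaps).
    """
    best = 0.0
    ok = False
    aligner = _make_aligner()
    for ref in references:
        alignment = aligner.align(candidate, ref)[0]
        row_a, row_b = alignment[0], alignment[1]
        identities = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
        aligned = sum(a != "-" and b != "-" for a, b in zip(row_a, row_b))
        identity = identities / len(row_a)
        coverage = aligned / len(candidate)
        best = max(best, identity)
        if identity >= identity_cutoff and coverage >= min_coverage:
            ok = True
    return ok, best


def validate_candidate(
    reverse_search: bool | None,
    topology_ok: bool,
    alignment_ok: bool,
    details: dict[str, str] | None = None,
) -> ValidationReport:
    """Apply the 2-of-3 rule; reverse-search evidence is injected from an
    external homology search and, when absent, counts as unsatisfied."""
    return ValidationReport(
        reverse_search=reverse_search,
        topology=topology_ok,
        alignment=alignment_ok,
        details=details or {},
    )


def trim_to_domains(residues: str, ecd_start: int, m4_end: int) -> str:
    """Truncate extraneous N/C-terminal domains to the pLGIC body.

    ``ecd_start`` typically comes from where the candidate starts aligning
    with a reference ECD; ``m4_end`` from the end of the last predicted TM
    segment.
    """
    if not 0 <= ecd_start < m4_end <= len(residues):
        raise ContractError(
            f"require 0 <= ecd_start < m4_end <= len, got "
            f"({ecd_start}, {m4_end}, {len(residues)})"
        )
    return residues[ecd_start:m4_end]
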
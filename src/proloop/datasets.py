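"""Taxonomically balanced dataset construction.

Protein databases are heavily dominated by metazoan pLGICs, so profile and
alignment building works from a balanced set: all microorganism sequences,
a uniform random subsample of the metazoan sequences (default 200, forming
a set of ~500 with the microorganisms), complemented with every metazoan
sequence whose Pro loop lacks one or both flanking cysteines (the Cys-less
completion), so that this rare class is never lost to subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TaxonTableError
from .io import GROUPS, TaxonTable
from .motifs import CYS_LOOP, CysStatus
from .records import SequenceRecord


@dataclass
class DatasetSpec:
    metazoan_sample_size: int = 200
    seed: int = 0
    include_all_cys_less_metazoa: bool = True

    def __post_init__(self) -> None:
        if self.metazoan_sample_size < 0:
            raise ValueError("metazoan_sample_size must be >= 0")


def assign_group(
    records: list[SequenceRecord],
    taxa: TaxonTable,
    on_missing: str = "error",
) -> dict[str, list[SequenceRecord]]:
    """Partition records by taxonomic group (disjoint and exhaustive).

    Unmapped ids raise listing all offenders, or are skipped with a warning
    under ``on_missing='skip'``.
    """
    partition: dict[str, list[SequenceRecord]] = {g: [] for g in GROUPS}
    missing = []
    for rec in records:
        group = taxa.group_of(rec.id)
        if group is None:
            missing.append(rec.id)
            continue
        partition[group].append(rec)
    if missing and on_missing == "error":
        raise TaxonTableError(
            f"{len(missing)} record(s) missing from taxon table: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return partition


def _status_value(status: "CysStatus | str") -> str:
    return status.value if isinstance(status, CysStatus) else status


def build_balanced_set(
    records: list[SequenceRecord],
    taxa: TaxonTable,
    spec: DatasetSpec,
    cys_status: dict[str, "CysStatus | str"] | None = None,
) -> list[SequenceRecord]:
    """All non-metazoans + a seeded uniform metazoan subsample + (optionally)
    every not-fully-Cys-loop metazoan; deduplicated by id, deterministic
    given the seed and input order.

    ``single_cys`` counts as Cys-less for the completion step ("lacked one
    or both of the cysteines").
    """
    partition = assign_group(records, taxa)
    metazoa = partition["metazoa"]
    microbes = [r for g in GROUPS if g != "metazoa" for r in partition[g]]

    rng = np.random.default_rng(spec.seed)
    k = min(spec.metazoan_sample_size, len(metazoa))
    sampled_idx = sorted(rng.choice(len(metazoa), size=k, replace=False).tolist())
    sampled = [metazoa[i] for i in sampled_idx]

    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in microbes + sampled:
        if rec.id not in seen:
            seen.add(rec.id)
            out.append(rec)
    if spec.include_all_cys_less_metazoa and cys_status is not None:
        for rec in metazoa:
            status = cys_status.get(rec.id)
            if status is not None and _status_value(status) != CYS_LOOP:
                if rec.id not in seen:
                    seen.add(rec.id)
                    out.append(rec)
    return out
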
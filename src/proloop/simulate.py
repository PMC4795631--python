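"""Synthetic-data generators with planted, self-checked truth.

Two generators back the test surface of the whole pipeline:

* :func:`simulate_alignment` emits a block-structured, pre-aligned protein
  family mimicking the pLGIC architecture — hydrophilic ECD carrying the
  [F/Y]PxD Pro-loop motif (with or without flanking cysteines per group),
  pre-M1 Arg, M1 with the W(1')/P(14') anchors, M2 with a group-appropriate
  selectivity triplet and Leu 9', the M2M3-loop proline, M3 with its 29'
  anchor, a variable-length cytoplasmic M3M4 loop realised as gap padding,
  and a hydrophobic M4.  Default group counts follow the composition of a
  broad cross-kingdom pLGIC survey (561 sequences: 218 metazoan of which 69
  Cys-less, 193 bacterial, 24 archaeal, 126 protist).  Blocks are generated
  as aligned columns directly, so no external aligner is involved.

* :func:`simulate_gene_family` evolves a gene family top-down along a rooted
  binary species tree with per-edge duplication and loss probabilities,
  recording every event, and returns the observed (pruned) gene tree in
  unrooted form together with the leaf map and the true root edge.

All randomness flows through the config seed; substitution noise draws from
a pool excluding P and C so planted motif and cysteine truths stay
well-defined under noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ProloopError
from .io import TaxonTable
from .motifs import (
    CYS_LESS,
    CYS_LOOP,
    call_selectivity,
    classify_cys_status,
    detect_proloop,
)
from .records import GAP, Alignment, SequenceRecord
from .trees import Tree, TreeNode, bipartition, unroot

# group key -> taxonomic group
GROUP_TAXON = {
    "metazoa_cys_loop_anionic": "metazoa",
    "metazoa_cys_loop_cationic": "metazoa",
    "metazoa_cys_less": "metazoa",
    "bacteria": "bacteria",
    "archaea": "archaea",
    "protist_cys_less": "protist",
    "protist_cys_loop": "protist",
}

CYS_LOOP_GROUPS = frozenset(
    {"metazoa_cys_loop_anionic", "metazoa_cys_loop_cationic", "protist_cys_loop"}
)

#: default composition: the survey's balanced-set group sizes
DEFAULT_COUNTS = {
    "metazoa_cys_loop_anionic": 75,
    "metazoa_cys_loop_cationic": 74,
    "metazoa_cys_less": 69,
    "bacteria": 193,
    "archaea": 24,
    "protist_cys_less": 100,
    "protist_cys_loop": 26,
}

HYDROPHOBIC = "LIVFMA"
POLAR = "DENQSTKGH"  # no P (keeps the planted motif leftmost), no C
NOISE_POOL = "ADEFGHIKLMNQRSTVWY"  # 20 aa minus P and C


@dataclass
class AlignmentSimConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    ecd_length: int = 210
    tm_lengths: tuple[int, int, int, int] = (26, 26, 29, 20)
    linker_length: int = 6
    m3m4_loop_length_distribution: tuple[float, float] = (110.0, 25.0)
    #: multiplicative loop-length factor for prokaryotes/Cys-less protists,
    #: whose cytoplasmic region is short or absent
    microbe_loop_factor: float = 0.1
    microbe_ecd_trim: int = 30
    substitution_noise_rate: dict[str, float] = field(
        default_factory=lambda: {"anchor": 0.0, "conserved": 0.0, "variable": 0.0}
    )
    m2_hydropathy_penalty: float = 0.35
    acidic_variant_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ContractError("group counts must be >= 0")
        unknown = set(self.counts) - set(GROUP_TAXON)
        if unknown:
            raise ContractError(f"unknown group keys: {sorted(unknown)}")
        if any(l < 5 for l in self.tm_lengths):
            raise ContractError("TM block lengths must be >= 5")
        if self.tm_lengths[0] < 26 or self.tm_lengths[1] < 26 or self.tm_lengths[2] < 29:
            raise ContractError("M1/M2 need >= 26 columns and M3 >= 29 for anchors")
        for k, v in self.substitution_noise_rate.items():
            if not 0 <= v <= 1:
                raise ContractError(f"noise rate {k}={v} outside [0, 1]")
        if self.ecd_length < self.microbe_ecd_trim + 80:
            raise ContractError("ECD too short for the motif region")


@dataclass
class SeqTruth:
    group: str
    taxon_group: str
    motif_start: int  # gapless, 0-based
    pattern: str
    is_acidic_variant: bool
    cys_up: int | None
    cys_down: int | None
    cys_status_label: str  # cys_loop | cys_less
    triplet: str  # as emitted (pre-noise design residues)
    selectivity_label: str
    anchors_gapless: dict[str, int]
    loop_length: int


@dataclass
class SimTruth:
    per_sequence: dict[str, SeqTruth]
    anchor_columns: dict[str, int]
    gappy_columns: list[int]
    tm_blocks: dict[str, tuple[int, int]]  # half-open column ranges
    reference_id: str
    reference_offsets: dict[str, int]  # anchor -> 1-based residue number

    def taxon_table(self) -> TaxonTable:
        table = TaxonTable()
        for seq_id, truth in self.per_sequence.items():
            table.add(seq_id, f"{truth.group}_species", truth.taxon_group)
        return table


def _loop_length(group: str, cfg: AlignmentSimConfig, rng: np.random.Generator,
                 loop_max: int) -> int:
    mean, disp = cfg.m3m4_loop_length_distribution
    if GROUP_TAXON[group] != "metazoa" and group != "protist_cys_loop":
        mean, disp = mean * cfg.microbe_loop_factor, disp * cfg.microbe_loop_factor
    return int(np.clip(round(rng.normal(mean, max(disp, 1e-9))), 0, loop_max))


def simulate_alignment(cfg: AlignmentSimConfig) -> tuple[Alignment, SimTruth]:
    """Emit a pre-aligned synthetic pLGIC family plus its planted truth.

    Deterministic per seed (byte-identical FASTA).  When the anchor noise
    rate is zero the generator verifies at emission time that the motif,
    Cys-status and selectivity annotators recover the planted truth exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    m1_len, m2_len, m3_len, m4_len = cfg.tm_lengths
    mean, disp = cfg.m3m4_loop_length_distribution
    loop_max = int(round(mean + 4 * disp))

    # --- column layout ------------------------------------------------
    ecd0 = 0
    motif_col = cfg.ecd_length - 40
    cys_up_col = motif_col - 8
    cys_down_col = motif_col + 3 + 6
    m1_0 = cfg.ecd_length
    link_0 = m1_0 + m1_len
    m2_0 = link_0 + cfg.linker_length
    m3_0 = m2_0 + m2_len
    loop_0 = m3_0 + m3_len
    m4_0 = loop_0 + loop_max
    n_cols = m4_0 + m4_len

    anchor_columns = {
        "m1_R26": m1_0,
        "m1_P14": m1_0 + 12,
        "m1_W1": m1_0 + 25,
        "m2_zero": m2_0,
        "m3_29": m3_0,
    }
    tm_blocks = {
        "M1": (m1_0, m1_0 + m1_len),
        "M2": (m2_0, m2_0 + m2_len),
        "M3": (m3_0, m3_0 + m3_len),
        "M4": (m4_0, m4_0 + m4_len),
    }

    # column noise classes
    anchor_cols = set(anchor_columns.values())
    anchor_cols.update(range(motif_col, motif_col + 4))
    anchor_cols.update({cys_up_col, cys_down_col})
    anchor_cols.update({m2_0 - 2, m2_0 - 1})          # triplet -2'/-1'
    anchor_cols.add(m2_0 + 9)                          # Leu 9'
    m2m3_pro_col = m2_0 + 21                           # M2M3-loop proline
    anchor_cols.add(m2m3_pro_col)
    conserved_cols = set()
    for start, end in tm_blocks.values():
        conserved_cols.update(range(start, end))
    conserved_cols -= anchor_cols

    def col_class(col: int) -> str:
        if col in anchor_cols:
            return "anchor"
        if col in conserved_cols:
            return "conserved"
        return "variable"

    # --- per-sequence rows --------------------------------------------
    ids: list[str] = []
    rows: list[list[str]] = []
    truths: dict[str, SeqTruth] = {}

    def pick(pool: str, size: int) -> list[str]:
        return [pool[i] for i in rng.integers(0, len(pool), size=size)]

    order = sorted(cfg.counts)
    for group in order:
        for i in range(cfg.counts[group]):
            seq_id = f"{group}_{i:04d}"
            taxon = GROUP_TAXON[group]
            is_microbe = taxon != "metazoa" and group != "protist_cys_loop"
            row = [GAP] * n_cols

            # ECD filler (polar), optionally trimmed for microbes
            ecd_start_col = ecd0 + (cfg.microbe_ecd_trim if is_microbe else 0)
            for col in range(ecd_start_col, cfg.ecd_length):
                row[col] = POLAR[rng.integers(0, len(POLAR))]

            # Pro-loop motif, flanking cysteines
            acidic = (
                group == "metazoa_cys_less"
                and rng.random() < cfg.acidic_variant_fraction
            )
            aromatic = "FY"[rng.integers(0, 2)]
            x_res = POLAR[rng.integers(0, len(POLAR))]
            motif = aromatic + "P" + x_res + ("E" if acidic else "D")
            for k, ch in enumerate(motif):
                row[motif_col + k] = ch
            has_cys = group in CYS_LOOP_GROUPS
            row[cys_up_col] = "C" if has_cys else "S"
            row[cys_down_col] = "C" if has_cys else "N"

            # M1: R 26', P 14', W 1', hydrophobic elsewhere
            for col in range(m1_0, m1_0 + m1_len):
                row[col] = HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]
            row[anchor_columns["m1_R26"]] = "R"
            row[anchor_columns["m1_P14"]] = "P"
            row[anchor_columns["m1_W1"]] = "W"

            # M1M2 linker; its last two columns carry -2'/-1'
            for col in range(link_0, m2_0):
                row[col] = POLAR[rng.integers(0, len(POLAR))]
            if group in ("metazoa_cys_loop_cationic", "protist_cys_loop") and \
                    group != "protist_cys_loop":
                design = "cationic"
            elif group == "protist_cys_loop":
                design = "cationic" if rng.random() < 0.5 else "anionic"
            elif group == "metazoa_cys_loop_anionic":
                design = "anionic"
            else:
                design = "none"
            if design == "cationic":
                triplet = "GE" + "KR"[rng.integers(0, 2)]
                selectivity = "cationic_type"
            elif design == "anionic":
                triplet = "PA" + "RK"[rng.integers(0, 2)]
                selectivity = "anionic_type"
            else:
                zero = "KR"[rng.integers(0, 2)] if rng.random() < 0.8 else "Q"
                triplet = "SN" + zero
                selectivity = "undetermined"
            row[m2_0 - 2], row[m2_0 - 1], row[m2_0] = triplet

            # M2: weakly hydrophobic, Leu 9', M2M3 Pro at 21'
            for col in range(m2_0 + 1, m2_0 + m2_len):
                pool = POLAR if rng.random() < cfg.m2_hydropathy_penalty else HYDROPHOBIC
                row[col] = pool[rng.integers(0, len(pool))]
            row[m2_0 + 9] = "L"
            row[m2m3_pro_col] = "P"

            # M3: 29' anchor (K anionic / P cationic / T otherwise), 24' aromatic
            for col in range(m3_0, m3_0 + m3_len):
                row[col] = HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]
            row[m3_0] = {"anionic": "K", "cationic": "P"}.get(design, "T")
            if taxon == "metazoa":
                row[m3_0 + 5] = "FY"[rng.integers(0, 2)]
            elif rng.random() < 0.65:
                row[m3_0 + 5] = "FYW"[rng.integers(0, 3)]

            # M3M4 loop: left-justified residues, gap padding
            loop_len = _loop_length(group, cfg, rng, loop_max)
            for col in range(loop_0, loop_0 + loop_len):
                row[col] = POLAR[rng.integers(0, len(POLAR))]

            # M4
            for col in range(m4_0, n_cols):
                row[col] = HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]

            # gapless truth coordinates (columns up to the loop are gap-free
            # apart from the microbe ECD trim)
            shift = cfg.microbe_ecd_trim if is_microbe else 0

            def gapless(col: int) -> int:
                return col - shift

            truths[seq_id] = SeqTruth(
                group=group,
                taxon_group=taxon,
                motif_start=gapless(motif_col),
                pattern=f"{aromatic}Px{'E' if acidic else 'D'}",
                is_acidic_variant=acidic,
                cys_up=gapless(cys_up_col) if has_cys else None,
                cys_down=gapless(cys_down_col) if has_cys else None,
                cys_status_label=CYS_LOOP if has_cys else CYS_LESS,
                triplet=triplet,
                selectivity_label=selectivity,
                anchors_gapless={k: gapless(c) for k, c in anchor_columns.items()},
                loop_length=loop_len,
            )
            ids.append(seq_id)
            rows.append(row)

    if not rows:
        raise ProloopError("no sequences requested")

    # --- substitution noise -------------------------------------------
    mat = np.array(rows, dtype="<U1")
    rates = cfg.substitution_noise_rate
    class_rate = np.array([rates.get(col_class(c), 0.0) for c in range(n_cols)])
    if class_rate.any():
        hit = (rng.random(mat.shape) < class_rate[None, :]) & (mat != GAP)
        repl = np.array(list(NOISE_POOL))[
            rng.integers(0, len(NOISE_POOL), size=mat.shape)
        ]
        mat = np.where(hit, repl, mat)

    records = [
        SequenceRecord(seq_id, "".join(row_chars), taxon_label=truths[seq_id].taxon_group)
        for seq_id, row_chars in zip(ids, mat)
    ]
    aln = Alignment(records)

    gap_frac = (aln.matrix() == GAP).mean(axis=0)
    gappy = np.flatnonzero(gap_frac > 0.5).tolist()

    # reference row: first bacterial sequence with a basic M2 0' residue
    # (matching the expected anchor identity); offsets are its 1-based
    # anchor residue numbers
    reference_id = next(
        (i for i in ids
         if truths[i].group == "bacteria" and truths[i].triplet[2] in "KR"),
        ids[0],
    )
    reference_offsets = {
        k: pos + 1 for k, pos in truths[reference_id].anchors_gapless.items()
    }

    truth = SimTruth(
        per_sequence=truths,
        anchor_columns=anchor_columns,
        gappy_columns=gappy,
        tm_blocks=tm_blocks,
        reference_id=reference_id,
        reference_offsets=reference_offsets,
    )

    if rates.get("anchor", 0.0) == 0.0:
        _self_check(aln, truth)
    return aln, truth


def _self_check(aln: Alignment, truth: SimTruth) -> None:
    """Generator output must satisfy its own truth (anchor noise = 0)."""
    for rec in aln:
        t = truth.per_sequence[rec.id]
        gapless = rec.ungapped()
        hit = detect_proloop(gapless)
        if hit is None or hit.start != t.motif_start or hit.pattern != t.pattern:
            raise ProloopError(f"self-check: motif truth violated for {rec.id}")
        status = classify_cys_status(gapless, hit)
        if status.value != t.cys_status_label:
            raise ProloopError(f"self-check: Cys truth violated for {rec.id}")
        if call_selectivity(t.triplet).value != t.selectivity_label:
            raise ProloopError(f"self-check: selectivity truth violated for {rec.id}")


# ---------------------------------------------------------------------------
# Gene family simulation


@dataclass
class GeneFamilySimConfig:
    species_tree: Tree
    duplication_rate: float = 0.0  # per species-tree edge, per lineage
    loss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ContractError("rates must be >= 0")
        if not self.species_tree.rooted:
            raise ContractError("species tree must be rooted")


@dataclass(frozen=True)
class Event:
    kind: str  # "duplication" | "loss"
    #: species-tree edge, identified by the leaf set below its child node
    species_edge: frozenset[str]


@dataclass
class GeneFamilySim:
    gene_tree: Tree  # unrooted (trifurcating top)
    rooted_tree: Tree  # the true rooted gene tree
    leafmap: dict[str, str]
    events: list[Event]
    true_root_edge: frozenset[str]  # bipartition, canonicalised
    attempts: int

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")


def random_species_tree(n_species: int, seed: int = 0) -> Tree:
    """A random rooted binary species tree with leaves S0..S{n-1}."""
    if n_species < 2:
        raise ContractError("need at least 2 species")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(f"S{i}") for i in range(n_species)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        parent = TreeNode()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return Tree(nodes[0], rooted=True)


def simulate_gene_family(cfg: GeneFamilySimConfig) -> GeneFamilySim:
    """Top-down birth-death along the species tree with a full event log.

    Each gene lineage entering a species-tree edge is lost with probability
    ``loss_rate``; a surviving lineage duplicates with probability
    ``duplication_rate`` (both copies then continue independently from the
    edge's child node).  Families whose observed tree has fewer than three
    leaves are discarded and regenerated with an incremented sub-seed; the
    attempt count is reported.
    """
    species = cfg.species_tree
    for attempt in range(1, 1001):
        rng = np.random.default_rng([cfg.seed % (2**31), attempt])
        events: list[Event] = []
        leafmap: dict[str, str] = {}
        counter: dict[str, int] = {}

        def edge_key(sp_node: TreeNode) -> frozenset[str]:
            return sp_node.leaf_labels()

        def descend(sp_node: TreeNode) -> TreeNode | None:
            if sp_node.is_leaf:
                k = counter.get(sp_node.label, 0) + 1
                counter[sp_node.label] = k
                leaf = TreeNode(f"{sp_node.label}_g{k}")
                leafmap[leaf.label] = sp_node.label
                return leaf
            kids = [enter_edge(c) for c in sp_node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]  # speciation suppressed (other side lost)
            node = TreeNode()
            for k in kids:
                node.add_child(k)
            return node

        def enter_edge(sp_node: TreeNode) -> TreeNode | None:
            if rng.random() < cfg.loss_rate:
                events.append(Event("loss", edge_key(sp_node)))
                return None
            if rng.random() < cfg.duplication_rate:
                events.append(Event("duplication", edge_key(sp_node)))
                left = descend(sp_node)
                right = descend(sp_node)
                if left is None and right is None:
                    return None
                if left is None or right is None:
                    return left or right
                node = TreeNode()
                node.add_child(left)
                node.add_child(right)
                return node
            return descend(sp_node)

        root = enter_edge(species.root)
        if root is None or root.is_leaf or len(root.leaves()) < 3:
            continue
        if len(root.children) != 2:
            continue
        rooted = Tree(root, rooted=True)
        labels = rooted.leaf_labels()
        true_root_edge = bipartition(root.children[0], labels)
        gene_unrooted = unroot(rooted)
        return GeneFamilySim(
            gene_tree=gene_unrooted,
            rooted_tree=rooted,
            leafmap=leafmap,
            events=events,
            true_root_edge=true_root_edge,
            attempts=attempt,
        )
    raise ProloopError("failed to simulate a surviving gene family in 1000 attempts")
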
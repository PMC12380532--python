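"""Data curation: quality filtering, clustering, MSA assembly, epitope
annotation, immunodominance (ID) scoring and the depth-based dataset split.

A *cluster* is a group of homologous antigen chains (>= 0.70 sequence
identity) bound by different antibodies. Epitopes are annotated per complex
(antigen residues with any heavy atom within 6 A of any antibody heavy
atom), mapped onto the cluster MSA, and summarized per column as the ID
score: the fraction of MSA rows in which that position is epitope-flagged.
Scores therefore live in [0, 1]; the profile is reported on the cluster
representative's residues. Representatives with MSA depth >= 10 form the
test set, depth 4-9 the training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .errors import AnnotationError, ConsistencyError, SplitError
from .io_formats import AlignedSequence, ComplexRecord, IDProfile

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class QualityFilterConfig:
    """Thresholds for structure quality filtering.

    Defaults mirror the curation recipe: resolution <= 3.0 A, R-factor
    <= 0.25, antigen chains of at least 50 residues, and removal of
    complexes whose antibody sequences are > 99% identical to an already
    retained complex.
    """

    max_resolution: float = 3.0
    max_r_factor: float = 0.25
    min_antigen_length: int = 50
    max_antibody_identity: float = 0.99

    def __post_init__(self) -> None:
        if min(self.max_resolution, self.max_r_factor, self.min_antigen_length) <= 0:
            raise ValueError("quality thresholds must be positive")
        if not 0.0 < self.max_antibody_identity <= 1.0:
            raise ValueError("max_antibody_identity must be in (0, 1]")


@dataclass
class AntigenCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str
    min_identity: float = 0.70
    min_members: int = 4

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ConsistencyError(
                f"{self.cluster_id}: representative {self.representative_id} not a member"
            )


@dataclass
class ClusterAlignment:
    """A per-cluster MSA whose rows carry epitope masks."""

    cluster_id: str
    rows: list[AlignedSequence]
    representative_row: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise ConsistencyError(f"{self.cluster_id}: empty alignment")
        lengths = {len(r.gapped_sequence) for r in self.rows}
        if len(lengths) > 1:
            raise ConsistencyError(f"{self.cluster_id}: ragged alignment")
        if not 0 <= self.representative_row < len(self.rows):
            raise ConsistencyError(f"{self.cluster_id}: representative_row out of range")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].gapped_sequence)

    @property
    def representative(self) -> AlignedSequence:
        return self.rows[self.representative_row]


@dataclass
class DatasetSplit:
    test_ids: set[str] = field(default_factory=set)
    train_ids: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Sequence identity and clustering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def global_alignment(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Best global alignment of two sequences as a pair of gapped strings."""
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length (gaps included)."""
    if not seq_a or not seq_b:
        return 0.0
    a, b = global_alignment(seq_a, seq_b)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def cluster_antigens(
    sequences: list[tuple[str, str]],
    min_identity: float = 0.70,
    min_members: int = 4,
) -> list[AntigenCluster]:
    """Greedy incremental clustering of antigen sequences.

    Sequences are visited longest first (ties broken by id); each joins the
    first existing cluster whose representative it matches at
    ``>= min_identity``, otherwise it founds a new cluster. Clusters smaller
    than ``min_members`` are discarded. For fidelity runs an external
    clustering (e.g. mmseqs2 easy-cluster output) can be ingested via
    :func:`bidkit.io_formats.read_clusters_tsv` instead.
    """
    if not sequences:
        return []
    ordered = sorted(sequences, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []  # (id, sequence) of each cluster representative
    members: list[list[str]] = []
    for seq_id, seq in ordered:
        placed = False
        for k, (_rep_id, rep_seq) in enumerate(reps):
            if sequence_identity(rep_seq, seq) >= min_identity:
                members[k].append(seq_id)
                placed = True
                break
        if not placed:
            reps.append((seq_id, seq))
            members.append([seq_id])
    clusters = []
    for k, (rep_id, _) in enumerate(reps):
        if len(members[k]) < min_members:
            continue
        clusters.append(
            AntigenCluster(
                cluster_id=f"cluster{len(clusters):03d}",
                member_ids=members[k],
                representative_id=rep_id,
                min_identity=min_identity,
                min_members=min_members,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def _antibody_sequence(record: ComplexRecord) -> str:
    return "".join(c.sequence for c in record.antibody_chains)


def quality_filter(
    records: list[ComplexRecord],
    cfg: QualityFilterConfig | None = None,
) -> list[ComplexRecord]:
    """Apply structure-quality and antibody-redundancy filters.

    A record is retained when resolution <= max_resolution, R-factor <=
    max_r_factor and every antigen chain has at least min_antigen_length
    residues; records missing resolution or R-factor are excluded with a
    logged reason. The survivors are then scanned in order of ascending
    resolution (ties by complex id) and a record is dropped when its
    concatenated antibody-chain sequence is more than max_antibody_identity
    identical to an already retained record.
    """
    cfg = cfg or QualityFilterConfig()
    passed: list[ComplexRecord] = []
    for rec in records:
        if rec.resolution is None or rec.r_factor is None:
            logger.info("%s excluded: missing resolution or R-factor", rec.complex_id)
            continue
        if rec.resolution > cfg.max_resolution:
            logger.info("%s excluded: resolution %.2f > %.2f",
                        rec.complex_id, rec.resolution, cfg.max_resolution)
            continue
        if rec.r_factor > cfg.max_r_factor:
            logger.info("%s excluded: R-factor %.3f > %.3f",
                        rec.complex_id, rec.r_factor, cfg.max_r_factor)
            continue
        short = [c.chain_id for c in rec.antigen_chains
                 if c.n_residues < cfg.min_antigen_length]
        if short:
            logger.info("%s excluded: antigen chain(s) %s shorter than %d",
                        rec.complex_id, short, cfg.min_antigen_length)
            continue
        passed.append(rec)

    passed.sort(key=lambda r: (r.resolution, r.complex_id))
    retained: list[ComplexRecord] = []
    retained_ab: list[str] = []
    for rec in passed:
        ab = _antibody_sequence(rec)
        redundant = any(
            sequence_identity(ab, prev) > cfg.max_antibody_identity for prev in retained_ab
        )
        if redundant:
            logger.info("%s excluded: antibody identity > %.2f to a retained record",
                        rec.complex_id, cfg.max_antibody_identity)
            continue
        retained.append(rec)
        retained_ab.append(ab)
    return retained


# ---------------------------------------------------------------------------
# Epitope annotation
# ---------------------------------------------------------------------------

def annotate_epitopes(
    record: ComplexRecord, cutoff: float = 6.0
) -> dict[str, np.ndarray]:
    """Flag antigen residues with any heavy atom within ``cutoff`` A (closed
    boundary) of any antibody heavy atom.

    Returns one boolean mask per antigen chain, length equal to the chain.
    """
    ab_coords = [c.atom_coords for c in record.antibody_chains if c.atom_coords.size]
    if not ab_coords:
        raise AnnotationError(f"{record.complex_id}: antibody chains have no coordinates")
    tree = cKDTree(np.vstack(ab_coords))
    masks: dict[str, np.ndarray] = {}
    for chain in record.antigen_chains:
        if chain.atom_coords.size == 0:
            raise AnnotationError(
                f"{record.complex_id} chain {chain.chain_id}: no coordinates"
            )
        dmin, _ = tree.query(chain.atom_coords)
        atom_hit = dmin <= cutoff
        mask = np.zeros(chain.n_residues, dtype=bool)
        np.logical_or.at(mask, chain.atom_residue, atom_hit)
        masks[chain.chain_id] = mask
    return masks


# ---------------------------------------------------------------------------
# MSA assembly (center-star) and epitope mapping
# ---------------------------------------------------------------------------

def center_star_msa(
    center: tuple[str, str], others: list[tuple[str, str]]
) -> list[AlignedSequence]:
    """Align every sequence to the center via pairwise global alignment and
    merge ("once a gap, always a gap"). Adequate for closely related cluster
    members; externally built alignments can be ingested with read_msa.

    Rows are returned center first, then ``others`` in input order.
    """
    center_id, center_seq = center
    n = len(center_seq)
    # Each row is stored as 2n+1 segments: slot0, res0, slot1, res1, ..., slotn
    slot_widths = [0] * (n + 1)
    stored: list[tuple[str, list[str], list[str]]] = []  # (id, slots, residue_chars)

    def decompose(center_gapped: str, other_gapped: str) -> tuple[list[str], list[str]]:
        slots = [""] * (n + 1)
        res_chars = [""] * n
        k = 0
        for c_ch, o_ch in zip(center_gapped, other_gapped):
            if c_ch == "-":
                slots[k] += o_ch
            else:
                res_chars[k] = o_ch
                k += 1
        return slots, res_chars

    for seq_id, seq in others:
        c_gapped, o_gapped = global_alignment(center_seq, seq)
        slots, res_chars = decompose(c_gapped, o_gapped)
        stored.append((seq_id, slots, res_chars))
        for k in range(n + 1):
            slot_widths[k] = max(slot_widths[k], len(slots[k]))

    def assemble(slots: list[str], res_chars: list[str]) -> str:
        parts = []
        for k in range(n):
            parts.append(slots[k].ljust(slot_widths[k], "-"))
            parts.append(res_chars[k])
        parts.append(slots[n].ljust(slot_widths[n], "-"))
        return "".join(parts)

    rows = [AlignedSequence(center_id, assemble([""] * (n + 1), list(center_seq)))]
    for seq_id, slots, res_chars in stored:
        rows.append(AlignedSequence(seq_id, assemble(slots, res_chars)))
    return rows


def build_cluster_alignment(
    cluster: AntigenCluster,
    msa_rows: list[AlignedSequence],
    masks: dict[str, np.ndarray],
) -> ClusterAlignment:
    """Attach per-member epitope masks to the cluster's MSA rows.

    Masks are defined on ungapped residues and attached by walking non-gap
    positions left to right; every cluster member must have a row and a mask
    of matching length.
    """
    by_id = {r.seq_id: r for r in msa_rows}
    missing = [m for m in cluster.member_ids if m not in by_id]
    if missing:
        raise ConsistencyError(f"{cluster.cluster_id}: MSA rows missing for {missing}")
    rows: list[AlignedSequence] = []
    for member in cluster.member_ids:
        row = by_id[member]
        if member not in masks:
            raise ConsistencyError(f"{cluster.cluster_id}: no epitope mask for {member}")
        mask = np.asarray(masks[member], dtype=bool)
        if mask.size != row.ungapped_length:
            raise ConsistencyError(
                f"{cluster.cluster_id}/{member}: mask length {mask.size} != "
                f"non-gap count {row.ungapped_length}"
            )
        rows.append(AlignedSequence(row.seq_id, row.gapped_sequence, epitope_mask=mask))
    rep_row = cluster.member_ids.index(cluster.representative_id)
    return ClusterAlignment(cluster_id=cluster.cluster_id, rows=rows,
                            representative_row=rep_row)


# ---------------------------------------------------------------------------
# ID scoring and dataset split
# ---------------------------------------------------------------------------

def compute_id_profile(
    alignment: ClusterAlignment,
    denominator: str = "total_rows",
) -> IDProfile:
    """Per-column ID score = (# rows epitope-flagged at the column) / depth.

    With ``denominator="total_rows"`` (default) the depth is the number of
    MSA rows, including rows gapped at the column; ``"nongap_rows"`` divides
    by the number of rows with a residue at the column instead. Columns where
    the representative is gapped are dropped, so the profile is indexed on
    the representative's ungapped residues.
    """
    if denominator not in ("total_rows", "nongap_rows"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    ncol = alignment.n_columns
    depth = alignment.depth
    flag_matrix = np.vstack([row.column_flags() for row in alignment.rows])
    nongap_matrix = np.vstack(
        [np.frombuffer(row.gapped_sequence.encode(), dtype="S1") != b"-"
         for row in alignment.rows]
    )
    counts_all = flag_matrix.sum(axis=0)
    rep = alignment.representative
    rep_cols = np.frombuffer(rep.gapped_sequence.encode(), dtype="S1") != b"-"
    counts = counts_all[rep_cols].astype(int)
    if denominator == "total_rows":
        denom = np.full(counts.shape, depth, dtype=int)
    else:
        denom = nongap_matrix.sum(axis=0)[rep_cols].astype(int)
    assert ncol == flag_matrix.shape[1]
    scores = counts / denom
    return IDProfile(
        antigen_id=rep.seq_id,
        scores=scores,
        msa_depth=depth,
        source_cluster=alignment.cluster_id,
        chain_id=rep.seq_id,
        sequence=rep.ungapped,
        epitope_counts=counts,
    )


def split_dataset(
    profiles: list[IDProfile],
    test_min_depth: int = 10,
    train_min_depth: int = 4,
) -> DatasetSplit:
    """Depth-based split: depth >= 10 -> test, 4 <= depth <= 9 -> train."""
    split = DatasetSplit()
    for p in profiles:
        if p.msa_depth < train_min_depth:
            raise SplitError(
                f"{p.antigen_id}: MSA depth {p.msa_depth} < {train_min_depth} "
                "(cluster minimum violated upstream)"
            )
        if p.msa_depth >= test_min_depth:
            split.test_ids.add(p.antigen_id)
        else:
            split.train_ids.add(p.antigen_id)
    return split
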
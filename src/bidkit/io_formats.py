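"""Readers, writers and in-memory records for every format the pipeline touches.

The pipeline works on antibody-antigen complex structures (PDB/mmCIF),
per-cluster multiple sequence alignments (aligned FASTA), per-residue
immunodominance (ID) profiles (CSV), chain-role and cluster-assignment
tables (TSV) and per-residue embedding matrices (CSV/NPY).

Internally everything is 0-based and contiguous per chain: author residue
numbering (including insertion codes) is resolved at parse time and kept
only as an annotation, never used in computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import AlignmentError, ConsistencyError, EmbeddingError, FormatError, RoleError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class ChainRole(str, Enum):
    """Role of a chain inside an antibody-antigen complex."""

    ANTIGEN = "antigen"
    ANTIBODY_HEAVY = "antibody_heavy"
    ANTIBODY_LIGHT = "antibody_light"
    ANTIBODY_SINGLE = "antibody_single"
    OTHER = "other"

    @property
    def is_antibody(self) -> bool:
        return self in (
            ChainRole.ANTIBODY_HEAVY,
            ChainRole.ANTIBODY_LIGHT,
            ChainRole.ANTIBODY_SINGLE,
        )


@dataclass
class ChainRecord:
    """One chain of a complex: sequence plus per-residue heavy-atom coordinates.

    Residue indices are 0-based and contiguous; ``atom_residue[i]`` maps atom
    ``i`` back to its residue. ``ca_coords`` rows are NaN where no CA atom was
    present.
    """

    chain_id: str
    role: ChainRole
    sequence: str
    atom_coords: np.ndarray          # (n_atoms, 3) float64, Angstrom
    atom_elements: np.ndarray        # (n_atoms,) unicode element symbols
    atom_names: np.ndarray           # (n_atoms,) unicode PDB atom names
    atom_residue: np.ndarray         # (n_atoms,) int, 0-based residue index
    ca_coords: np.ndarray            # (n_res, 3) float64, NaN if missing
    author_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_res = len(self.sequence)
        if self.ca_coords.shape != (n_res, 3):
            raise ConsistencyError(
                f"chain {self.chain_id}: ca_coords shape {self.ca_coords.shape} "
                f"!= ({n_res}, 3)"
            )
        if self.atom_residue.size and int(self.atom_residue.max()) >= n_res:
            raise ConsistencyError(f"chain {self.chain_id}: atom residue index out of range")
        if not np.isfinite(self.atom_coords).all():
            raise ConsistencyError(f"chain {self.chain_id}: non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_atom_coords(self, residue_index: int) -> np.ndarray:
        return self.atom_coords[self.atom_residue == residue_index]


@dataclass
class ComplexRecord:
    """One antibody-antigen complex with chain roles and quality metadata."""

    complex_id: str
    chains: list[ChainRecord]
    resolution: float | None = None
    r_factor: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        roles = [c.role for c in self.chains]
        if not any(r == ChainRole.ANTIGEN for r in roles):
            raise RoleError(f"{self.complex_id}: no antigen chain")
        if not any(r.is_antibody for r in roles):
            raise RoleError(f"{self.complex_id}: no antibody chain")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def antigen_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.role == ChainRole.ANTIGEN]

    @property
    def antibody_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.role.is_antibody]


@dataclass
class AlignedSequence:
    """One row of a cluster MSA; epitope flags live on non-gap positions."""

    seq_id: str
    gapped_sequence: str
    epitope_mask: np.ndarray | None = None  # bool, length == non-gap count

    def __post_init__(self) -> None:
        self.gapped_sequence = self.gapped_sequence.upper()
        if self.epitope_mask is not None:
            self.epitope_mask = np.asarray(self.epitope_mask, dtype=bool)
            if self.epitope_mask.size != self.ungapped_length:
                raise ConsistencyError(
                    f"{self.seq_id}: mask length {self.epitope_mask.size} != "
                    f"non-gap count {self.ungapped_length}"
                )

    @property
    def ungapped_length(self) -> int:
        return len(self.gapped_sequence) - self.gapped_sequence.count("-")

    @property
    def ungapped(self) -> str:
        return self.gapped_sequence.replace("-", "")

    def column_flags(self) -> np.ndarray:
        """Epitope flag per MSA column; False at gap columns."""
        flags = np.zeros(len(self.gapped_sequence), dtype=bool)
        if self.epitope_mask is None:
            return flags
        k = 0
        for i, ch in enumerate(self.gapped_sequence):
            if ch != "-":
                flags[i] = self.epitope_mask[k]
                k += 1
        return flags


@dataclass
class IDProfile:
    """Per-residue immunodominance scores on a cluster representative.

    ``scores[i] == epitope_counts[i] / msa_depth`` exactly; the integer counts
    are kept so downstream checks can use rational arithmetic.
    """

    antigen_id: str
    scores: np.ndarray               # float in [0, 1], length n_res
    msa_depth: int
    source_cluster: str = ""
    chain_id: str = ""
    sequence: str = ""
    epitope_counts: np.ndarray | None = None  # int, same length

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and (self.scores.min() < 0.0 or self.scores.max() > 1.0):
            raise ConsistencyError(f"{self.antigen_id}: ID scores outside [0, 1]")
        if self.epitope_counts is not None:
            self.epitope_counts = np.asarray(self.epitope_counts, dtype=int)
            if self.epitope_counts.shape != self.scores.shape:
                raise ConsistencyError(f"{self.antigen_id}: counts/scores length mismatch")

    def __len__(self) -> int:
        return self.scores.size


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: the highest-occupancy altloc (ties: first seen)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def _parse_r_factor(path: Path) -> float | None:
    """Best-effort R-work extraction from PDB REMARK 3 or mmCIF _refine."""
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif"):
            doc = gemmi.cif.read(str(path))
            block = doc.sole_block()
            for tag in ("_refine.ls_R_factor_R_work", "_refine.ls_R_factor_obs"):
                val = block.find_value(tag)
                if val not in (None, "?", "."):
                    return float(val)
            return None
        with open(path) as fh:
            for line in fh:
                if line.startswith("REMARK   3") and "R VALUE" in line and ":" in line:
                    tail = line.rsplit(":", 1)[1].strip()
                    try:
                        return float(tail)
                    except ValueError:
                        continue
    except Exception:  # noqa: BLE001 - metadata is optional
        return None
    return None


def _chain_from_gemmi(chain: gemmi.Chain, role: ChainRole,
                      source: str) -> ChainRecord | None:
    seq_chars: list[str] = []
    coords: list[list[float]] = []
    elements: list[str] = []
    names: list[str] = []
    atom_res: list[int] = []
    ca_rows: list[np.ndarray] = []
    author_numbers: list[str] = []
    for residue in chain:
        info = gemmi.find_tabulated_residue(residue.name)
        if info is None or not info.is_amino_acid():
            continue
        atoms = _resolve_altlocs(residue)
        if not atoms:
            warnings.warn(
                f"{source} {chain.name} {residue.name}{residue.seqid}: "
                "no coordinates, residue skipped",
                stacklevel=2,
            )
            continue
        idx = len(seq_chars)
        seq_chars.append(THREE_TO_ONE.get(residue.name, "X"))
        author_numbers.append(f"{residue.seqid.num}{residue.seqid.icode}".strip())
        ca = np.full(3, np.nan)
        for atom in atoms:
            if atom.element.name == "H":
                continue
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            elements.append(atom.element.name)
            names.append(atom.name)
            atom_res.append(idx)
            if atom.name == "CA":
                ca = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        ca_rows.append(ca)
    if not seq_chars:
        return None
    return ChainRecord(
        chain_id=chain.name,
        role=role,
        sequence="".join(seq_chars),
        atom_coords=np.asarray(coords, dtype=float).reshape(-1, 3),
        atom_elements=np.asarray(elements, dtype="U4"),
        atom_names=np.asarray(names, dtype="U6"),
        atom_residue=np.asarray(atom_res, dtype=int),
        ca_coords=np.vstack(ca_rows),
        author_numbers=author_numbers,
    )


def read_chain(path: str | Path, chain_id: str,
               role: ChainRole = ChainRole.ANTIGEN) -> ChainRecord:
    """Read a single chain from a PDB/mmCIF file (no role invariants)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    st.remove_hydrogens()
    for chain in st[0]:
        if chain.name == chain_id:
            parsed = _chain_from_gemmi(chain, role, path.name)
            if parsed is None:
                raise FormatError(f"{path.name}: chain {chain_id} has no residues")
            return parsed
    raise FormatError(f"{path.name}: chain {chain_id} not found")


def read_complex(
    path: str | Path,
    chain_roles: Mapping[str, ChainRole | str],
    complex_id: str | None = None,
) -> ComplexRecord:
    """Read a PDB/mmCIF file into a :class:`ComplexRecord`.

    Hydrogens are dropped, altlocs resolved to the highest occupancy, and
    residues without coordinates skipped with a warning. Only chains listed
    in ``chain_roles`` are kept; the roles must include at least one antigen
    and one antibody chain.
    """
    path = Path(path)
    roles = {cid: ChainRole(role) for cid, role in chain_roles.items()}
    if not any(r == ChainRole.ANTIGEN for r in roles.values()):
        raise RoleError(f"{path.name}: chain_roles contain no antigen chain")
    if not any(r.is_antibody for r in roles.values()):
        raise RoleError(f"{path.name}: chain_roles contain no antibody chain")

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    st.remove_hydrogens()
    model = st[0]

    chains: list[ChainRecord] = []
    for chain in model:
        if chain.name not in roles:
            continue
        parsed = _chain_from_gemmi(chain, roles[chain.name], path.name)
        if parsed is not None:
            chains.append(parsed)

    missing = sorted(set(roles) - {c.chain_id for c in chains})
    if missing:
        raise FormatError(f"{path.name}: chains {missing} not found in structure")

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return ComplexRecord(
        complex_id=complex_id or path.stem,
        chains=chains,
        resolution=resolution,
        r_factor=_parse_r_factor(path),
        method=getattr(st, "experimental_method", "") or "",
    )


def write_pdb(record: ComplexRecord, path: str | Path) -> None:
    """Write a ComplexRecord as a minimal, deterministic PDB file."""
    lines: list[str] = []
    if record.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.{record.resolution:8.2f} ANGSTROMS.")
    if record.r_factor is not None:
        lines.append(
            "REMARK   3   R VALUE            (WORKING SET) : "
            f"{record.r_factor:.3f}"
        )
    serial = 1
    for chain in record.chains:
        for res_idx in range(chain.n_residues):
            aa = chain.sequence[res_idx]
            resname = ONE_TO_THREE.get(aa, "UNK")
            sel = chain.atom_residue == res_idx
            for name, element, xyz in zip(
                chain.atom_names[sel], chain.atom_elements[sel], chain.atom_coords[sel]
            ):
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {resname:<3s} "
                    f"{chain.chain_id[:1]}{res_idx + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {ONE_TO_THREE.get(chain.sequence[-1], 'UNK'):<3s} "
                     f"{chain.chain_id[:1]}{chain.n_residues:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA / MSA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Plain FASTA reader returning (id, uppercase sequence) pairs."""
    records: list[tuple[str, str]] = []
    seq_id: str | None = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seq_id is not None:
                    records.append((seq_id, "".join(parts).upper()))
                seq_id = line[1:].split()[0]
                parts = []
            else:
                if seq_id is None:
                    raise FormatError(f"{path}: sequence data before first header")
                parts.append(line)
    if seq_id is not None:
        records.append((seq_id, "".join(parts).upper()))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_msa(path: str | Path) -> list[AlignedSequence]:
    """Read an aligned FASTA file; all rows must share the gapped length."""
    records = read_fasta(path)
    if not records:
        return []
    lengths = {len(seq) for _, seq in records}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return [AlignedSequence(seq_id=sid, gapped_sequence=seq) for sid, seq in records]


def write_msa(rows: Sequence[AlignedSequence], path: str | Path) -> None:
    write_fasta([(r.seq_id, r.gapped_sequence) for r in rows], path)


# ---------------------------------------------------------------------------
# ID profile CSV
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["chain_id", "residue_index_0based", "aa", "id_score", "msa_depth"]


def write_id_profile(profile: IDProfile, path: str | Path) -> None:
    """Write an ID profile as CSV; round-trips losslessly via read_id_profile."""
    n = len(profile)
    seq = profile.sequence or "X" * n
    df = pd.DataFrame(
        {
            "chain_id": [profile.chain_id or profile.antigen_id] * n,
            "residue_index_0based": np.arange(n, dtype=int),
            "aa": list(seq),
            "id_score": [repr(float(s)) for s in profile.scores],
            "msa_depth": [profile.msa_depth] * n,
        },
        columns=PROFILE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_id_profile(path: str | Path, antigen_id: str | None = None) -> IDProfile:
    df = pd.read_csv(path, dtype={"chain_id": str, "aa": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing profile columns {missing}")
    if len(df) == 0:
        return IDProfile(antigen_id=antigen_id or Path(path).stem, scores=np.zeros(0),
                         msa_depth=0, epitope_counts=np.zeros(0, dtype=int))
    depth = int(df["msa_depth"].iloc[0])
    scores = df["id_score"].to_numpy(dtype=float)
    counts = np.rint(scores * depth).astype(int) if depth > 0 else np.zeros(len(df), dtype=int)
    return IDProfile(
        antigen_id=antigen_id or str(df["chain_id"].iloc[0]),
        scores=scores,
        msa_depth=depth,
        chain_id=str(df["chain_id"].iloc[0]),
        sequence="".join(df["aa"].astype(str)),
        epitope_counts=counts,
    )


# ---------------------------------------------------------------------------
# Tabular sidecar formats
# ---------------------------------------------------------------------------

def read_roles_tsv(path: str | Path) -> dict[str, dict[str, ChainRole]]:
    """Read a chain-role table: complex_id <tab> chain_id <tab> role."""
    out: dict[str, dict[str, ChainRole]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated fields")
            cid, chain_id, role = parts
            try:
                out.setdefault(cid, {})[chain_id] = ChainRole(role)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: unknown role {role!r}") from exc
    return out


def write_roles_tsv(roles: Mapping[str, Mapping[str, ChainRole]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(roles):
            for chain_id in sorted(roles[cid]):
                fh.write(f"{cid}\t{chain_id}\t{roles[cid][chain_id].value}\n")


def read_clusters_tsv(path: str | Path) -> list[tuple[str, list[str], str]]:
    """Read cluster assignments: cluster_id <tab> member_id <tab> is_representative."""
    clusters: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated fields")
            cluster_id, member_id, is_rep = parts
            if cluster_id not in clusters:
                clusters[cluster_id] = []
                order.append(cluster_id)
            clusters[cluster_id].append(member_id)
            if is_rep.strip().lower() in ("1", "true", "yes"):
                reps[cluster_id] = member_id
    out = []
    for cid in order:
        rep = reps.get(cid, clusters[cid][0])
        out.append((cid, clusters[cid], rep))
    return out


def write_clusters_tsv(clusters: Sequence[tuple[str, Sequence[str], str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cluster_id, members, rep in clusters:
            for m in members:
                fh.write(f"{cluster_id}\t{m}\t{1 if m == rep else 0}\n")


# ---------------------------------------------------------------------------
# Embedding matrices
# ---------------------------------------------------------------------------

def read_embedding_matrix(path: str | Path) -> np.ndarray:
    """Read a per-residue embedding matrix from .npy or CSV (no header)."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise EmbeddingError(f"{path}: expected a 2-D matrix, got shape {arr.shape}")
    return arr


def write_embedding_matrix(matrix: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if path.suffix == ".npy":
        np.save(path, matrix)
    else:
        np.savetxt(path, matrix, delimiter=",", fmt="%.10g")
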
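"""Per-residue and per-patch surface features for the immunodominance analysis.

Features: relative solvent accessibility (RSA) from a built-in Shrake-Rupley
SASA, 3-state secondary structure (built-in dihedral assignment or an
external DSSP adapter), geometric protrusion/depth proxies, nine
physico-chemical amino-acid scales, an MSA-entropy conservation proxy, and
10 A surface patches with the neighbor-ID statistic (mean ID score of patch
members excluding the center).

Surface residues are those with RSA >= 0.10 (closed boundary). SASA is
computed on the antigen chain in isolation so epitope residues are not
artifactually buried by the bound antibody.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import ComplexRecord, ChainRecord, IDProfile
from .curation import ClusterAlignment

logger = logging.getLogger(__name__)

SURFACE_RSA_THRESHOLD = 0.10
PATCH_RADIUS = 10.0

#: Van der Waals radii (A) used by the SASA computation.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4

#: Theoretical maximum accessible surface areas (A^2), Tien et al. 2013.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
_GENERIC_MAX_ASA = float(np.mean(list(MAX_ASA.values())))

#: Nine physico-chemical scales over the 20 standard amino acids. One fixed
#: published AAIndex entry per feature (IDs documented in docs/methods.md);
#: the table can be overridden by passing a custom mapping to aa_scales.
AA_SCALE_NAMES = [
    "hydrophobicity", "isoelectric_point", "residue_volume", "steric",
    "polarizability", "h_bond_donor", "polarity", "positive_charge",
    "negative_charge",
]

AA_SCALES: dict[str, dict[str, float]] = {
    # Kyte-Doolittle hydropathy (KYTJ820101)
    "hydrophobicity": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    # Zimmerman isoelectric point (ZIMJ680104)
    "isoelectric_point": {
        "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65,
        "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
        "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.66, "W": 5.89,
        "Y": 5.66, "V": 5.96,
    },
    # Grantham side-chain volume (GRAR740103)
    "residue_volume": {
        "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
        "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
        "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
        "Y": 136.0, "V": 84.0,
    },
    # Charton steric parameter (CHAM810101)
    "steric": {
        "A": 0.52, "R": 0.68, "N": 0.76, "D": 0.76, "C": 0.62, "Q": 0.68,
        "E": 0.68, "G": 0.00, "H": 0.70, "I": 1.02, "L": 0.98, "K": 0.68,
        "M": 0.78, "F": 0.70, "P": 0.36, "S": 0.53, "T": 0.50, "W": 0.70,
        "Y": 0.70, "V": 0.76,
    },
    # Charton-Charton polarizability (CHAM820101)
    "polarizability": {
        "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
        "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
        "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
        "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
    },
    # Fauchere et al. number of hydrogen-bond donors (FAUJ880109)
    "h_bond_donor": {
        "A": 0.0, "R": 4.0, "N": 2.0, "D": 1.0, "C": 1.0, "Q": 2.0,
        "E": 1.0, "G": 0.0, "H": 1.0, "I": 0.0, "L": 0.0, "K": 2.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 1.0, "T": 1.0, "W": 1.0,
        "Y": 1.0, "V": 0.0,
    },
    # Grantham polarity (GRAR740102)
    "polarity": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
        "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
        "Y": 6.2, "V": 5.9,
    },
    # Fauchere et al. positive charge (FAUJ880111)
    "positive_charge": {
        "A": 0.0, "R": 1.0, "N": 0.0, "D": 0.0, "C": 0.0, "Q": 0.0,
        "E": 0.0, "G": 0.0, "H": 0.5, "I": 0.0, "L": 0.0, "K": 1.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
        "Y": 0.0, "V": 0.0,
    },
    # Fauchere et al. negative charge (FAUJ880112)
    "negative_charge": {
        "A": 0.0, "R": 0.0, "N": 0.0, "D": 1.0, "C": 0.0, "Q": 0.0,
        "E": 1.0, "G": 0.0, "H": 0.0, "I": 0.0, "L": 0.0, "K": 0.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
        "Y": 0.0, "V": 0.0,
    },
}


def aa_scales(aa: str, table: dict[str, dict[str, float]] | None = None) -> dict[str, float]:
    """Nine physico-chemical scale values for one amino acid.

    Unknown or nonstandard residues ('X') get NaN for every scale.
    """
    table = table or AA_SCALES
    return {name: table[name].get(aa, float("nan")) for name in AA_SCALE_NAMES}


# ---------------------------------------------------------------------------
# SASA / RSA (Shrake-Rupley with a deterministic Fibonacci sphere)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    elements: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley style.

    Deterministic given ``n_points``: test points are a fixed Fibonacci
    lattice on each atom's expanded sphere (vdW radius + probe); a point is
    accessible when outside every neighbour's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[0]
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    sasa = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * sphere
        neighbors = tree.query_ball_point(coords[i], r=radii[i] + rmax)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return sasa


def compute_rsa(
    record: ComplexRecord,
    chain_id: str,
    n_points: int = 960,
) -> np.ndarray:
    """Per-residue relative solvent accessibility of one chain.

    The SASA is computed on the chain in isolation (other chains, including
    the antibody, removed) and normalized by a fixed per-amino-acid maximum
    ASA table. Values can slightly exceed 1 for highly exposed residues in
    small peptides.
    """
    chain = record.chain(chain_id)
    return chain_rsa(chain, n_points=n_points)


def chain_rsa(chain: ChainRecord, n_points: int = 960) -> np.ndarray:
    sasa = atom_sasa(chain.atom_coords, chain.atom_elements, n_points=n_points)
    rsa = np.zeros(chain.n_residues)
    per_res = np.zeros(chain.n_residues)
    np.add.at(per_res, chain.atom_residue, sasa)
    for i, aa in enumerate(chain.sequence):
        rsa[i] = per_res[i] / MAX_ASA.get(aa, _GENERIC_MAX_ASA)
    return rsa


# ---------------------------------------------------------------------------
# Secondary structure (3-state)
# ---------------------------------------------------------------------------

def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_atoms(chain: ChainRecord) -> dict[str, np.ndarray]:
    """Per-residue N/CA/C coordinate arrays, NaN where missing."""
    out = {name: np.full((chain.n_residues, 3), np.nan) for name in ("N", "CA", "C")}
    for name in ("N", "CA", "C"):
        sel = chain.atom_names == name
        out[name][chain.atom_residue[sel]] = chain.atom_coords[sel]
    return out

def backbone_dihedrals(chain: ChainRecord) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) in degrees; NaN where backbone atoms are missing."""
    bb = _backbone_atoms(chain)
    n = chain.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0 and not np.isnan([bb["C"][i - 1], bb["N"][i], bb["CA"][i], bb["C"][i]]).any():
            phi[i] = _dihedral(bb["C"][i - 1], bb["N"][i], bb["CA"][i], bb["C"][i])
        if i < n - 1 and not np.isnan([bb["N"][i], bb["CA"][i], bb["C"][i], bb["N"][i + 1]]).any():
            psi[i] = _dihedral(bb["N"][i], bb["CA"][i], bb["C"][i], bb["N"][i + 1])
    return phi, psi


def assign_ss3(record: ComplexRecord, chain_id: str, min_run: int = 3) -> np.ndarray:
    """Built-in 3-state secondary structure from backbone dihedrals.

    Residues fall in the helical region (phi in [-100, -30], psi in [-80, 0])
    or the extended region (phi in [-180, -45], psi in [45, 180] or below
    -135); runs shorter than ``min_run`` collapse to coil. Residues without
    backbone atoms are assigned coil with a warning. For fidelity runs, use
    :func:`parse_dssp` / :func:`collapse_ss8` on external DSSP output.
    """
    chain = record.chain(chain_id)
    phi, psi = backbone_dihedrals(chain)
    n = chain.n_residues
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        warnings.warn(f"chain {chain_id}: missing backbone atoms, affected residues set to coil",
                      stacklevel=2)
    cand = np.full(n, "C", dtype="U1")
    for i in range(n):
        ph, ps = phi[i], psi[i]
        # Terminal residues lack one angle; classify on the available one.
        if np.isnan(ph) and np.isnan(ps):
            continue
        helix_phi = (-100.0 <= ph <= -30.0) if not np.isnan(ph) else True
        helix_psi = (-80.0 <= ps <= 0.0) if not np.isnan(ps) else True
        strand_phi = (-180.0 <= ph <= -45.0) if not np.isnan(ph) else True
        strand_psi = ((45.0 <= ps <= 180.0) or (ps <= -135.0)) if not np.isnan(ps) else True
        if helix_phi and helix_psi and not (np.isnan(ph) and np.isnan(ps)):
            cand[i] = "H"
        elif strand_phi and strand_psi:
            cand[i] = "E"
    # enforce minimum run lengths
    out = cand.copy()
    i = 0
    while i < n:
        j = i
        while j < n and cand[j] == cand[i]:
            j += 1
        if cand[i] in ("H", "E") and (j - i) < min_run:
            out[i:j] = "C"
        i = j
    mapping = {"H": "helix", "E": "strand", "C": "coil"}
    return np.array([mapping[c] for c in out], dtype="U6")


SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "coil", "S": "coil", "-": "coil", " ": "coil", "C": "coil", "P": "coil",
}


def collapse_ss8(letters: str | list[str]) -> np.ndarray:
    """Collapse DSSP 8-state letters to 3 states (H,G,I->helix; E,B->strand)."""
    return np.array([SS8_TO_SS3.get(ch, "coil") for ch in letters], dtype="U6")


def parse_dssp(path, chain_id: str | None = None) -> np.ndarray:
    """Read 8-state letters for one chain from a classic DSSP output file.

    Returns the per-residue 3-state assignment (H,G,I->helix; E,B->strand;
    everything else coil); chain breaks ('!') are skipped.
    """
    letters: list[str] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_data = True
                continue
            if not in_data or len(line) < 17:
                continue
            if line[13] == "!":
                continue
            if chain_id is not None and line[11].strip() != chain_id:
                continue
            letters.append(line[16])
    return collapse_ss8(letters)


# ---------------------------------------------------------------------------
# Geometric proxies
# ---------------------------------------------------------------------------

def geometric_proxies(
    record: ComplexRecord,
    chain_id: str,
    radius: float = 10.0,
    n_points: int = 960,
) -> tuple[np.ndarray, np.ndarray]:
    """Protrusion and depth proxies for each residue of a chain.

    protrusion = 1 - (heavy-atom count within ``radius`` of the residue
    centroid) / (maximum such count over the chain): 1 marks the most exposed
    tip, 0 the densest environment. depth = distance (A) from the residue
    centroid to the nearest solvent-accessible atom (atom SASA > 0) of the
    chain; surface residues get small values, core residues large ones.
    """
    return chain_geometric_proxies(record.chain(chain_id), radius=radius,
                                   n_points=n_points)


def chain_geometric_proxies(
    chain: ChainRecord,
    radius: float = 10.0,
    n_points: int = 960,
) -> tuple[np.ndarray, np.ndarray]:
    n = chain.n_residues
    if n == 1:
        warnings.warn(f"chain {chain.chain_id}: single residue, proxies set to 0",
                      stacklevel=2)
        return np.zeros(1), np.zeros(1)
    centroids = np.zeros((n, 3))
    for i in range(n):
        centroids[i] = chain.residue_atom_coords(i).mean(axis=0)
    tree = cKDTree(chain.atom_coords)
    counts = np.array([len(tree.query_ball_point(c, r=radius)) for c in centroids], dtype=float)
    protrusion = 1.0 - counts / counts.max()
    sasa = atom_sasa(chain.atom_coords, chain.atom_elements, n_points=n_points)
    accessible = chain.atom_coords[sasa > 0.0]
    if accessible.shape[0] == 0:
        depth = np.zeros(n)
    else:
        acc_tree = cKDTree(accessible)
        depth, _ = acc_tree.query(centroids)
    return protrusion, np.asarray(depth, dtype=float)


# ---------------------------------------------------------------------------
# Conservation proxy
# ---------------------------------------------------------------------------

def conservation_proxy(alignment: ClusterAlignment) -> np.ndarray:
    """Normalized Shannon entropy per representative column, in [0, 1].

    0 = perfectly conserved column, 1 = uniform over the 20 amino acids.
    Gaps are excluded from the distribution. Returned on the representative's
    ungapped residue coordinates, like the ID profile.
    """
    rep = alignment.representative
    values = []
    rows = [r.gapped_sequence for r in alignment.rows]
    for col, ch in enumerate(rep.gapped_sequence):
        if ch == "-":
            continue
        counts: dict[str, int] = {}
        for row in rows:
            c = row[col]
            if c != "-" and c != "X":
                counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        if total <= 1:
            values.append(0.0)
            continue
        p = np.array(list(counts.values()), dtype=float) / total
        entropy = -(p * np.log(p)).sum()
        values.append(entropy / np.log(20.0))
    return np.asarray(values)


# ---------------------------------------------------------------------------
# Feature table and surface patches
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = (
    ["residue_index", "aa", "rsa", "ss3", "protrusion", "depth"]
    + AA_SCALE_NAMES
    + ["conservation", "id_score"]
)


def build_feature_table(
    record: ComplexRecord,
    chain_id: str,
    profile: IDProfile | None = None,
    alignment: ClusterAlignment | None = None,
    n_points: int = 960,
) -> pd.DataFrame:
    """Assemble the per-residue feature table for one antigen chain."""
    chain = record.chain(chain_id)
    n = chain.n_residues
    rsa = chain_rsa(chain, n_points=n_points)
    ss3 = assign_ss3(record, chain_id)
    protrusion, depth = geometric_proxies(record, chain_id, n_points=n_points)
    rows = {
        "residue_index": np.arange(n, dtype=int),
        "aa": list(chain.sequence),
        "rsa": rsa,
        "ss3": ss3,
        "protrusion": protrusion,
        "depth": depth,
    }
    for name in AA_SCALE_NAMES:
        rows[name] = [AA_SCALES[name].get(aa, np.nan) for aa in chain.sequence]
    if alignment is not None:
        cons = conservation_proxy(alignment)
        if cons.size != n:
            raise ValueError(
                f"conservation length {cons.size} != chain length {n}"
            )
        rows["conservation"] = cons
    else:
        rows["conservation"] = np.full(n, np.nan)
    if profile is not None:
        if len(profile) != n:
            raise ValueError(f"profile length {len(profile)} != chain length {n}")
        rows["id_score"] = profile.scores
    else:
        rows["id_score"] = np.full(n, np.nan)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


@dataclass
class SurfacePatch:
    """Surface residues within ``radius`` A of a central surface residue."""

    center_index: int
    member_indices: list[int]
    radius: float
    patch_features: dict[str, float]
    patch_id_score: float
    neighbor_id: float  # NaN when the patch is just its center

    def __post_init__(self) -> None:
        if self.center_index not in self.member_indices:
            raise ValueError("patch center must be a member")


def build_patches(
    features: pd.DataFrame,
    ca_coords: np.ndarray,
    radius: float = PATCH_RADIUS,
    surface_threshold: float = SURFACE_RSA_THRESHOLD,
) -> list[SurfacePatch]:
    """One patch per surface residue: surface residues within ``radius`` of
    the center by CA-CA distance, center included.

    ``patch_features`` is the arithmetic mean of the members' numeric
    features; ``neighbor_id`` is the members' mean ID score excluding the
    center (NaN for singleton patches).
    """
    surface_idx = features.index[features["rsa"] >= surface_threshold].to_numpy()
    if surface_idx.size == 0:
        return []
    coords = np.asarray(ca_coords, dtype=float)[surface_idx]
    if np.isnan(coords).any():
        raise ValueError("patch construction requires CA coordinates for surface residues")
    tree = cKDTree(coords)
    numeric = [c for c in features.columns
               if c not in ("residue_index", "aa", "ss3") and
               pd.api.types.is_numeric_dtype(features[c])]
    patches: list[SurfacePatch] = []
    for local_i, center in enumerate(surface_idx):
        neighbors_local = sorted(tree.query_ball_point(coords[local_i], r=radius))
        members = [int(surface_idx[j]) for j in neighbors_local]
        sub = features.loc[members, numeric]
        patch_features = {c: float(sub[c].mean()) for c in numeric}
        center_id = float(features.loc[center, "id_score"])
        others = [m for m in members if m != center]
        neighbor_id = (
            float(features.loc[others, "id_score"].mean()) if others else float("nan")
        )
        patches.append(
            SurfacePatch(
                center_index=int(center),
                member_indices=members,
                radius=radius,
                patch_features=patch_features,
                patch_id_score=center_id,
                neighbor_id=neighbor_id,
            )
        )
    return patches


def patch_table(patches: list[SurfacePatch]) -> pd.DataFrame:
    """Flatten patches into a per-patch feature table (one row per center)."""
    if not patches:
        return pd.DataFrame()
    rows = []
    for p in patches:
        row = {"center_index": p.center_index, "patch_size": len(p.member_indices),
               "id_score": p.patch_id_score, "neighbor_id": p.neighbor_id}
        for k, v in p.patch_features.items():
            if k != "id_score":
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
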
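"""Fully synthetic antibody-antigen fixtures with the statistical structure
the pipeline assumes.

A synthetic cluster is one antigen backbone (shared coordinates) bound, in
each member complex, by a pseudo-antibody: a small cloud of atoms docked
onto a *footprint* of spatially contiguous surface residues. Footprints are
reused across members with a configurable probability, so some surface
positions accumulate high epitope frequency (high ID) while others stay
weak, producing ID profiles with sharp peaks and flat regions. Member
sequences differ by i.i.d. point mutations at a rate low enough that the
cluster survives 0.70-identity clustering.

Every member's epitope mask is *geometrically consistent*: it is exactly the
set of antigen residues with a heavy atom within 6 A of the pseudo-antibody,
the same contract the curation module's annotator uses. The ground-truth ID
profile is the per-column mask frequency, kept as integer counts so the
pipeline's output can be compared in exact rational arithmetic.

Pseudo-antibodies are atom clouds, not immunoglobulins; every downstream
computation sees only atoms and distances, so nothing more is needed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    STANDARD_AA,
    ChainRecord,
    ChainRole,
    ComplexRecord,
    IDProfile,
    write_fasta,
    write_id_profile,
    write_pdb,
    write_roles_tsv,
    write_clusters_tsv,
    write_embedding_matrix,
)

EPITOPE_CUTOFF = 6.0


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the study conditions.

    chain_length 120 and cluster sizes 4-15 mirror the curated-data regime
    (antigens of at least 50 residues; clusters of 4+ complexes with test
    clusters at depth >= 10). mutation_rate 0.05 keeps members well above
    the 0.70 clustering identity. 2-4 footprints of ~9 A radius reused with
    probability 0.6 yield both high-ID peaks and weakly hit positions.
    """

    seed: int = 0
    chain_length: int = 120
    cluster_size_range: tuple[int, int] = (4, 15)
    mutation_rate: float = 0.05
    n_footprints_range: tuple[int, int] = (2, 4)
    footprint_radius: float = 9.0
    footprint_reuse_prob: float = 0.6
    coordinate_model: str = "helix_bundle"   # or "random_walk"
    embedding_aware: bool = False
    embedding_dim: int = 8
    embedding_noise: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate < 0.30:
            raise ValueError("mutation_rate must be < 0.30 to respect 0.70 clustering")
        if self.footprint_radius <= 0:
            raise ValueError("footprint_radius must be positive")
        if self.chain_length < 50:
            raise ValueError("chain_length must be >= 50 (antigen size filter)")


@dataclass
class SyntheticTruth:
    """Generator ground truth for one cluster."""

    cluster_id: str
    member_masks: np.ndarray          # (depth, n_res) bool
    footprint_centers: list[int]
    footprint_assignment: list[int]   # per member

    @property
    def depth(self) -> int:
        return self.member_masks.shape[0]

    @property
    def epitope_counts(self) -> np.ndarray:
        return self.member_masks.sum(axis=0).astype(int)

    @property
    def true_id(self) -> np.ndarray:
        return self.epitope_counts / self.depth


@dataclass
class SyntheticCluster:
    cluster_id: str
    records: list[ComplexRecord]
    truth: SyntheticTruth
    representative_index: int = 0
    embedding: np.ndarray | None = None      # planted latent, (n_res, d)
    modulated_id: np.ndarray | None = None   # embedding-aware targets, (n_res,)

    @property
    def representative(self) -> ComplexRecord:
        return self.records[self.representative_index]

    @property
    def representative_chain(self) -> ChainRecord:
        return self.representative.antigen_chains[0]

    def true_profile(self) -> IDProfile:
        rep = self.representative_chain
        return IDProfile(
            antigen_id=self.representative.complex_id + ":A",
            scores=self.truth.true_id,
            msa_depth=self.truth.depth,
            source_cluster=self.cluster_id,
            chain_id="A",
            sequence=rep.sequence,
            epitope_counts=self.truth.epitope_counts,
        )


@dataclass
class SyntheticCorpus:
    config: SyntheticConfig
    clusters: list[SyntheticCluster] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Backbone geometry
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place atom D given three predecessors (natural extension reference
    frame): |CD| = r, angle(B,C,D) = theta, torsion(A,B,C,D) = tau."""
    theta, tau = np.radians(theta_deg), np.radians(tau_deg)
    b1 = (b - a) / np.linalg.norm(b - a)
    b2 = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2)
    d = r * (-np.cos(theta) * b2 + np.sin(theta) * (np.cos(tau) * m + np.sin(tau) * n))
    return c + d


def ideal_peptide(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    omega: float = 180.0,
    chain_id: str = "A",
    role: ChainRole = ChainRole.ANTIGEN,
) -> ChainRecord:
    """Peptide with ideal backbone geometry at fixed (phi, psi) dihedrals.

    Atoms per residue: N, CA, C, O, plus CB for non-glycine. The default
    angles are a canonical alpha-helix; (-120, 130) gives an extended strand.
    Used as a geometry fixture for secondary-structure and SASA checks.
    """
    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (1.458, 0.0, 0.0)
    ang = np.radians(180.0 - 111.2)
    C[0] = CA[0] + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], 1.329, 116.2, psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], 1.458, 121.7, omega)
        C[i] = _nerf(C[i - 1], N[i], CA[i], 1.525, 111.2, phi)
    coords, elements, names, atom_res, ca_rows = [], [], [], [], []
    for i in range(n_res):
        per_res = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i])]
        # carbonyl O in the peptide plane, opposite the next N
        o_tau = psi - 180.0
        O = _nerf(N[i], CA[i], C[i], 1.231, 120.8, o_tau)
        per_res.append(("O", "O", O))
        if sequence[i] != "G":
            CB = _nerf(C[i], N[i], CA[i], 1.530, 110.5, 122.6)
            per_res.append(("CB", "C", CB))
        for name, el, xyz in per_res:
            names.append(name)
            elements.append(el)
            coords.append(xyz)
            atom_res.append(i)
        ca_rows.append(CA[i])
    return ChainRecord(
        chain_id=chain_id, role=role, sequence=sequence,
        atom_coords=np.asarray(coords), atom_elements=np.asarray(elements, dtype="U4"),
        atom_names=np.asarray(names, dtype="U6"), atom_residue=np.asarray(atom_res),
        ca_coords=np.asarray(ca_rows),
    )


def _solenoid_ca_trace(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """CA trace along a superhelical (solenoid) curve: a minor helix wound on
    a slowly rising helical axis, so successive turns stack and bury a core.
    Points are placed by arc-length stepping at 3.8 A."""
    axis_r = 6.0
    axis_omega = 2.0 * np.pi / 24.0
    axis_rise = 9.0 / 24.0
    minor_r = 2.3
    minor_omega = np.radians(100.0)
    phase = rng.uniform(0, 2 * np.pi)

    def pos(u: float) -> np.ndarray:
        ax = np.array([axis_r * np.cos(axis_omega * u + phase),
                       axis_r * np.sin(axis_omega * u + phase),
                       axis_rise * u])
        # frame: tangent of the axis, radial normal, binormal
        t = np.array([-axis_r * axis_omega * np.sin(axis_omega * u + phase),
                      axis_r * axis_omega * np.cos(axis_omega * u + phase),
                      axis_rise])
        t /= np.linalg.norm(t)
        nrm = np.array([np.cos(axis_omega * u + phase),
                        np.sin(axis_omega * u + phase), 0.0])
        b = np.cross(t, nrm)
        b /= np.linalg.norm(b)
        return ax + minor_r * (np.cos(minor_omega * u) * nrm + np.sin(minor_omega * u) * b)

    points = [pos(0.0)]
    u = 0.0
    for _ in range(1, n_res):
        lo, hi = u, u + 3.0
        while np.linalg.norm(pos(hi) - points[-1]) < 3.8:
            hi += 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(pos(mid) - points[-1]) < 3.8:
                lo = mid
            else:
                hi = mid
        u = 0.5 * (lo + hi)
        points.append(pos(u))
    return np.asarray(points)


def _random_walk_ca_trace(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding walk with 3.8 A steps inside a sphere."""
    r_max = 3.3 * n_res ** (1.0 / 3.0)
    points = [np.zeros(3)]
    direction = _random_unit(rng)
    while len(points) < n_res:
        placed = False
        for _ in range(120):
            cand_dir = direction + 0.9 * _random_unit(rng)
            cand_dir /= np.linalg.norm(cand_dir)
            cand = points[-1] + 3.8 * cand_dir
            if np.linalg.norm(cand) > r_max:
                continue
            if len(points) > 1:
                d = np.linalg.norm(np.asarray(points[:-1]) - cand, axis=1)
                if (d < 4.0).any():
                    continue
            points.append(cand)
            direction = cand_dir
            placed = True
            break
        if not placed:  # back off and retry from an earlier residue
            points = points[: max(1, len(points) - 5)]
            direction = _random_unit(rng)
            r_max *= 1.02
    return np.asarray(points)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _chain_from_ca_trace(ca: np.ndarray, sequence: str, chain_id: str = "A",
                         role: ChainRole = ChainRole.ANTIGEN) -> ChainRecord:
    """Decorate a CA trace with pseudo N, C, O, CB atoms from local frames."""
    n = ca.shape[0]
    centroid = ca.mean(axis=0)
    coords, elements, names, atom_res = [], [], [], []
    for i in range(n):
        u = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        v = ca[i + 1] - ca[i] if i < n - 1 else ca[i] - ca[i - 1]
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        w = np.cross(u, v)
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(u, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(w) < 1e-6:
                w = np.cross(u, np.array([0.0, 1.0, 0.0]))
        w /= np.linalg.norm(w)
        lo = np.asarray(
            [ca[max(0, i - 2) : min(n, i + 3)].mean(axis=0)]
        )[0]
        out = ca[i] - lo
        if np.linalg.norm(out) < 1e-6:
            out = ca[i] - centroid
        out /= np.linalg.norm(out)
        per_res = [
            ("N", "N", ca[i] - 1.2 * u + 0.6 * w),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + 1.2 * v + 0.6 * w),
            ("O", "O", ca[i] + 1.2 * v + 1.8 * w),
            ("CB", "C", ca[i] + 1.53 * out),
        ]
        for name, el, xyz in per_res:
            names.append(name)
            elements.append(el)
            coords.append(xyz)
            atom_res.append(i)
    return ChainRecord(
        chain_id=chain_id, role=role, sequence=sequence,
        atom_coords=np.asarray(coords), atom_elements=np.asarray(elements, dtype="U4"),
        atom_names=np.asarray(names, dtype="U6"), atom_residue=np.asarray(atom_res),
        ca_coords=np.asarray(ca, dtype=float),
    )


def generate_antigen(cfg: SyntheticConfig, rng: np.random.Generator | None = None
                     ) -> ChainRecord:
    """One synthetic antigen chain: random sequence on a compact backbone.

    ``helix_bundle`` mode winds the chain on a solenoid so that a buried core
    exists and RSA spans the full range; ``random_walk`` gives an irregular
    compact globule. Consecutive CA atoms are 3.8 A apart by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sequence = "".join(rng.choice(list(STANDARD_AA), size=cfg.chain_length))
    if cfg.coordinate_model == "helix_bundle":
        ca = _solenoid_ca_trace(cfg.chain_length, rng)
    elif cfg.coordinate_model == "random_walk":
        ca = _random_walk_ca_trace(cfg.chain_length, rng)
    else:
        raise ValueError(f"unknown coordinate_model {cfg.coordinate_model!r}")
    return _chain_from_ca_trace(ca, sequence)


# ---------------------------------------------------------------------------
# Pseudo-antibodies and clusters
# ---------------------------------------------------------------------------

_AB_N_RESIDUES = 10
_AB_ATOMS_PER_RES = 3


def _place_antibody(
    antigen: ChainRecord,
    footprint_residues: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Atom cloud docked onto a footprint: centered along the outward normal,
    pushed to a contact distance that yields epitopes without clashes."""
    fp_ca = antigen.ca_coords[footprint_residues]
    centroid = fp_ca.mean(axis=0)
    outward = centroid - antigen.ca_coords.mean(axis=0)
    outward /= np.linalg.norm(outward)
    n_atoms = _AB_N_RESIDUES * _AB_ATOMS_PER_RES
    cloud = rng.normal(scale=2.2, size=(n_atoms, 3))
    cloud -= cloud.mean(axis=0)
    # slide along the normal until the closest approach is ~4.0 A
    for dist in np.arange(2.0, 25.0, 0.25):
        atoms = centroid + dist * outward + cloud
        diff = atoms[:, None, :] - antigen.atom_coords[None, :, :]
        dmin = np.sqrt((diff ** 2).sum(-1)).min()
        if dmin >= 4.0:
            return atoms
    return centroid + 25.0 * outward + cloud


def _antibody_chain(atoms: np.ndarray, sequence: str) -> ChainRecord:
    n_res = _AB_N_RESIDUES
    atom_res = np.repeat(np.arange(n_res), _AB_ATOMS_PER_RES)
    names = np.tile(np.array(["CA", "CB", "CG"], dtype="U6"), n_res)
    ca = atoms[names == "CA"]
    return ChainRecord(
        chain_id="H", role=ChainRole.ANTIBODY_SINGLE, sequence=sequence,
        atom_coords=atoms, atom_elements=np.full(atoms.shape[0], "C", dtype="U4"),
        atom_names=names, atom_residue=atom_res, ca_coords=ca,
    )


def _epitope_mask(antigen: ChainRecord, ab_atoms: np.ndarray,
                  cutoff: float = EPITOPE_CUTOFF) -> np.ndarray:
    """6 A heavy-atom rule, brute force (the shared geometric contract)."""
    diff = antigen.atom_coords[:, None, :] - ab_atoms[None, :, :]
    hit = (np.sqrt((diff ** 2).sum(-1)) <= cutoff).any(axis=1)
    mask = np.zeros(antigen.n_residues, dtype=bool)
    np.logical_or.at(mask, antigen.atom_residue, hit)
    return mask


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in STANDARD_AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _surface_indices(antigen: ChainRecord, threshold: float = 0.10) -> np.ndarray:
    from .surface import chain_rsa

    rsa = chain_rsa(antigen, n_points=240)  # coarse but deterministic: selection only
    return np.flatnonzero(rsa >= threshold)


def generate_cluster(
    cfg: SyntheticConfig,
    cluster_id: str = "syn000",
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ComplexRecord], SyntheticTruth]:
    """One synthetic cluster: ``depth`` complexes of the same antigen bound by
    pseudo-antibodies on reused footprints.

    Footprint centers are sampled on surface residues (RSA >= 0.10) so the
    high-ID signal is surface-biased. Each member either reuses an
    already-used footprint (probability ``footprint_reuse_prob``; the
    antibody placement is deterministic per footprint, so reuse reproduces
    the mask exactly) or takes the next unused candidate, cycling when
    exhausted. Representative = member 0 (unmutated sequence).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if depth is None:
        depth = int(rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1))
    antigen = generate_antigen(cfg, rng)
    surface = _surface_indices(antigen)
    if surface.size < 8:
        raise RuntimeError(f"{cluster_id}: too few surface residues for footprints")
    n_fp = int(rng.integers(cfg.n_footprints_range[0], cfg.n_footprints_range[1] + 1))
    n_fp = min(n_fp, surface.size)
    centers = rng.choice(surface, size=n_fp, replace=False)
    footprints = []
    ab_atoms_per_fp = []
    for k, center in enumerate(centers):
        d = np.linalg.norm(antigen.ca_coords[surface] - antigen.ca_coords[center], axis=1)
        fp = surface[d <= cfg.footprint_radius]
        footprints.append(fp)
        stable_id = zlib.crc32(cluster_id.encode()) & 0x7FFFFFFF
        ab_atoms_per_fp.append(
            _place_antibody(antigen, fp, np.random.default_rng(
                np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, stable_id, k])))
        )

    records: list[ComplexRecord] = []
    masks = np.zeros((depth, antigen.n_residues), dtype=bool)
    assignment: list[int] = []
    used: list[int] = []
    next_unused = 0
    for j in range(depth):
        if used and rng.random() < cfg.footprint_reuse_prob:
            k = used[rng.integers(len(used))]
        else:
            k = next_unused % n_fp
            next_unused += 1
        if k not in used:
            used.append(k)
        assignment.append(int(k))
        ab_atoms = ab_atoms_per_fp[k]
        masks[j] = _epitope_mask(antigen, ab_atoms)
        seq = antigen.sequence if j == 0 else _mutate(antigen.sequence, cfg.mutation_rate, rng)
        member_antigen = ChainRecord(
            chain_id="A", role=ChainRole.ANTIGEN, sequence=seq,
            atom_coords=antigen.atom_coords, atom_elements=antigen.atom_elements,
            atom_names=antigen.atom_names, atom_residue=antigen.atom_residue,
            ca_coords=antigen.ca_coords,
        )
        ab_seq = "".join(rng.choice(list(STANDARD_AA), size=_AB_N_RESIDUES))
        records.append(
            ComplexRecord(
                complex_id=f"{cluster_id}_m{j}",
                chains=[member_antigen, _antibody_chain(ab_atoms, ab_seq)],
                resolution=float(np.round(rng.uniform(1.5, 2.8), 2)),
                r_factor=float(np.round(rng.uniform(0.16, 0.24), 3)),
                method="X-RAY DIFFRACTION",
            )
        )
    truth = SyntheticTruth(
        cluster_id=cluster_id,
        member_masks=masks,
        footprint_centers=[int(c) for c in centers],
        footprint_assignment=assignment,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def planted_weights(cfg: SyntheticConfig) -> np.ndarray:
    """Corpus-wide linear readout weights of the planted latent; fixed by the
    corpus seed so one global decoder exists across clusters."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x9E3779B9])
    )
    w = rng.normal(size=cfg.embedding_dim)
    return w / np.linalg.norm(w)


def plant_embedding_targets(
    cluster: SyntheticCluster, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Planted latent vectors and the modulated regression targets.

    The latent ``z`` is spatially smoothed per-residue Gaussian noise (two
    rounds of 10 A neighborhood averaging), so it carries the spatial
    clustering the real embeddings would. The modulated target is
    ``sigmoid(3.5 (Az . w) + 14 (A rsa - 0.22))`` where ``A`` is one further
    round of neighborhood averaging and ``w`` are corpus-wide weights: a
    known linear function of the planted latent field plus a patch-level
    exposure term (both spatially clustered, the regime where neighborhood
    attention helps). The emitted embedding is ``z`` plus
    ``embedding_noise`` Gaussian jitter. Parameter recovery (can a trained
    model invert the map on held-out clusters?) is therefore well-posed,
    structure-only embeddings retain partial signal, and one-hot encodings
    none.
    """
    from .surface import chain_rsa

    chain = cluster.representative_chain
    n = chain.n_residues
    z = rng.normal(size=(n, cfg.embedding_dim))
    adj = _adjacency(chain.ca_coords)
    for _ in range(2):
        z = adj @ z
    z *= 3.0  # restore spread lost to smoothing
    w = planted_weights(cfg)
    rsa = chain_rsa(chain, n_points=240)
    u = 3.5 * ((adj @ z) @ w) + 14.0 * (adj @ rsa - 0.22)
    target = 1.0 / (1.0 + np.exp(-u))
    emitted = z + cfg.embedding_noise * rng.normal(size=z.shape)
    return emitted, target


def _adjacency(ca: np.ndarray, radius: float = 10.0) -> np.ndarray:
    """Row-normalized neighborhood-averaging operator (self included)."""
    from scipy.spatial.distance import pdist, squareform

    a = (squareform(pdist(ca)) <= radius).astype(float)
    np.fill_diagonal(a, 1.0)
    return a / a.sum(axis=1, keepdims=True)


def generate_dataset(
    cfg: SyntheticConfig,
    n_clusters: int = 20,
    depth_distribution: tuple[tuple[int, int], tuple[int, int]] = ((4, 9), (10, 14)),
    test_fraction: float = 0.5,
    out_dir: str | Path | None = None,
) -> SyntheticCorpus:
    """A corpus of synthetic clusters with a controlled train/test depth mix.

    The first ``round(test_fraction * n_clusters)`` clusters draw their depth
    from the test range (default 10-14), the rest from the train range (4-9).
    With ``embedding_aware`` configs each cluster also carries a planted
    latent embedding for its representative. When ``out_dir`` is given, the
    corpus is written to disk (complexes/*.pdb, sequences.fasta, roles.tsv,
    clusters.tsv, truth/*.csv, embeddings/*.csv), fully determined by
    ``cfg.seed``.
    """
    root_seq = np.random.SeedSequence(cfg.seed)
    children = root_seq.spawn(n_clusters + 1)
    emb_rng = np.random.default_rng(children[-1])
    corpus = SyntheticCorpus(config=cfg)
    n_test = int(round(test_fraction * n_clusters))
    for i in range(n_clusters):
        rng = np.random.default_rng(children[i])
        lo, hi = depth_distribution[1] if i < n_test else depth_distribution[0]
        depth = int(rng.integers(lo, hi + 1))
        cid = f"syn{i:03d}"
        records, truth = generate_cluster(cfg, cluster_id=cid, depth=depth, rng=rng)
        cluster = SyntheticCluster(cluster_id=cid, records=records, truth=truth)
        if cfg.embedding_aware:
            cluster.embedding, cluster.modulated_id = plant_embedding_targets(
                cluster, cfg, emb_rng)
        corpus.clusters.append(cluster)
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "complexes").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    roles: dict[str, dict[str, ChainRole]] = {}
    fasta: list[tuple[str, str]] = []
    cluster_rows = []
    if corpus.config.embedding_aware:
        (out / "embeddings").mkdir(exist_ok=True)
    for cluster in corpus.clusters:
        member_ids = []
        for rec in cluster.records:
            write_pdb(rec, out / "complexes" / f"{rec.complex_id}.pdb")
            roles[rec.complex_id] = {c.chain_id: c.role for c in rec.chains}
            ag = rec.antigen_chains[0]
            fasta.append((f"{rec.complex_id}:A", ag.sequence))
            member_ids.append(f"{rec.complex_id}:A")
        rep_id = f"{cluster.representative.complex_id}:A"
        cluster_rows.append((cluster.cluster_id, member_ids, rep_id))
        write_id_profile(cluster.true_profile(), out / "truth" / f"{cluster.cluster_id}.csv")
        if cluster.embedding is not None:
            write_embedding_matrix(cluster.embedding,
                                   out / "embeddings" / f"{cluster.cluster_id}.csv")
        if cluster.modulated_id is not None:
            (out / "targets").mkdir(exist_ok=True)
            np.savetxt(out / "targets" / f"{cluster.cluster_id}.csv",
                       cluster.modulated_id, fmt="%.10g")
    write_roles_tsv(roles, out / "roles.tsv")
    write_fasta(fasta, out / "sequences.fasta")
    write_clusters_tsv(cluster_rows, out / "clusters.tsv")
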
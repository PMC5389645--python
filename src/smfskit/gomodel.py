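"""Native-topology (Go-type) coarse-grained model construction.

A protein chain is reduced to one bead per residue at the Cα position.
Residue pairs in contact in the native structure attract through a
Lennard-Jones well of uniform depth ε with its minimum at the native
separation; all other non-bonded pairs only repel.  Chain connectivity is
maintained by harmonic bonds and angles and a native-biased 1x/3x cosine
dihedral term.

Residue indices are 1-based sequence positions along the selected chain;
``residue_numbers`` keeps the author numbering of the source PDB so that
domain ranges can be given in either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CGStructure",
    "ContactMap",
    "GoHamiltonian",
    "parse_structure",
    "build_contact_map",
    "build_hamiltonian",
    "energy_forces",
    "write_contact_map",
]

HEAVY_ATOM_CUTOFF_A = 4.5
CALPHA_CUTOFF_A = 8.0
MIN_SEQ_SEPARATION = 3
BACKBONE_GAP_A = 4.5  # successive Cα beyond this -> chain break


@dataclass
class CGStructure:
    """Cα bead representation of one chain."""

    coords_A: np.ndarray  # (N, 3)
    chain_id: str = "A"
    residue_numbers: list[int] | None = None  # author numbering, len N
    domain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    heavy_atoms: list[np.ndarray] | None = None  # per-residue heavy-atom coords

    def __post_init__(self) -> None:
        self.coords_A = np.asarray(self.coords_A, dtype=float)
        if self.coords_A.ndim != 2 or self.coords_A.shape[1] != 3:
            raise ValueError("coords_A must be an (N, 3) array")
        if self.residue_numbers is None:
            self.residue_numbers = list(range(1, self.n_residues + 1))
        if len(self.residue_numbers) != self.n_residues:
            raise ValueError("residue_numbers length mismatch")
        gaps = self.backbone_gaps()
        if gaps:
            raise ValueError(
                "broken backbone: successive Cα gaps > "
                f"{BACKBONE_GAP_A} Å after positions {gaps}"
            )
        n = self.n_residues
        for name, (a, b) in self.domain_ranges.items():
            if not (1 <= a <= b):
                raise ValueError(f"domain {name}: invalid range {a}..{b}")
            if b > max(self.residue_numbers):
                raise ValueError(f"domain {name}: range exceeds chain")

    @property
    def n_residues(self) -> int:
        return self.coords_A.shape[0]

    def backbone_gaps(self) -> list[int]:
        d = np.linalg.norm(np.diff(self.coords_A, axis=0), axis=1)
        return [i + 1 for i in np.nonzero(d > BACKBONE_GAP_A)[0]]

    def domain_mask(self, name: str) -> np.ndarray:
        """Boolean mask over beads for a named domain (author numbering)."""
        a, b = self.domain_ranges[name]
        nums = np.asarray(self.residue_numbers)
        return (nums >= a) & (nums <= b)

    def domain_end_to_end_A(self, name: str, coords: np.ndarray | None = None) -> float:
        """Distance between the first and last residue of a domain."""
        coords = self.coords_A if coords is None else coords
        idx = np.nonzero(self.domain_mask(name))[0]
        return float(np.linalg.norm(coords[idx[-1]] - coords[idx[0]]))


@dataclass
class ContactMap:
    """Native contacts as 1-based (i, j, r0) triples with i < j, |i−j| ≥ 3."""

    pairs: list[tuple[int, int, float]]
    method: Literal["heavy_atom", "calpha"]
    cutoff_A: float

    def __post_init__(self) -> None:
        seen = set()
        for i, j, r0 in self.pairs:
            if i >= j or j - i < MIN_SEQ_SEPARATION:
                raise ValueError(f"invalid contact pair ({i}, {j})")
            if r0 <= 0:
                raise ValueError("native distance must be positive")
            if (i, j) in seen:
                raise ValueError(f"duplicate contact pair ({i}, {j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    def partner_counts(self, n_residues: int) -> np.ndarray:
        """Number of contact partners per residue (1-based positions)."""
        counts = np.zeros(n_residues, dtype=int)
        for i, j, _ in self.pairs:
            counts[i - 1] += 1
            counts[j - 1] += 1
        return counts


def parse_structure(
    pdb_text: str,
    chain: str | None = None,
    domain_ranges: Mapping[str, tuple[int, int]] | None = None,
) -> CGStructure:
    """Extract a Cα bead chain (plus heavy atoms) from PDB text.

    Only ATOM records of the selected chain are used (first chain if none
    given); alternate locations resolve to the highest-occupancy conformer;
    residues lacking a Cα are skipped and reported.  A backbone gap larger
    than 4.5 Å between successive Cα positions raises an error naming the
    gap positions.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    chain_obj = None
    for ch in model:
        if chain is None or ch.name == chain:
            chain_obj = ch
            break
    if chain_obj is None:
        raise ValueError(f"chain {chain!r} not found")

    coords: list[np.ndarray] = []
    numbers: list[int] = []
    heavy: list[np.ndarray] = []
    skipped: list[str] = []
    for res in chain_obj:
        if res.het_flag != "A":  # ATOM records only
            continue
        ca_best = None
        heavy_pos = []
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            heavy_pos.append(pos)
            if atom.name == "CA":
                if ca_best is None or atom.occ > ca_best[0]:
                    ca_best = (atom.occ, pos)
        if ca_best is None:
            skipped.append(f"{res.name}{res.seqid.num}")
            continue
        coords.append(ca_best[1])
        numbers.append(res.seqid.num)
        heavy.append(np.array(heavy_pos))
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "skipped %d residue(s) without Cα: %s", len(skipped), ", ".join(skipped)
        )
    if not coords:
        raise ValueError("no Cα atoms found in the selected chain")
    return CGStructure(
        coords_A=np.array(coords),
        chain_id=chain_obj.name,
        residue_numbers=numbers,
        domain_ranges=dict(domain_ranges or {}),
        heavy_atoms=heavy,
    )


def build_contact_map(
    structure: CGStructure,
    method: Literal["heavy_atom", "calpha"] = "heavy_atom",
    cutoff_A: float | None = None,
) -> ContactMap:
    """Native contacts of a structure.

    heavy_atom: residues i, j (|i−j| ≥ 3) are in contact if any pair of
    their heavy atoms lies within the cutoff (default 4.5 Å) — a distance
    proxy for surface-complementarity contact determination.
    calpha: Cα–Cα distance within the cutoff (default 8.0 Å), for bead-only
    structures.  In both cases r0 is the native Cα–Cα distance.
    """
    n = structure.n_residues
    if method == "heavy_atom":
        if structure.heavy_atoms is None:
            raise ValueError("heavy_atom contact method requires heavy atoms")
        cutoff = HEAVY_ATOM_CUTOFF_A if cutoff_A is None else cutoff_A
        points = np.concatenate(structure.heavy_atoms)
        owner = np.concatenate(
            [np.full(len(a), k) for k, a in enumerate(structure.heavy_atoms)]
        )
        tree = cKDTree(points)
        residue_pairs = set()
        for a, b in tree.query_pairs(cutoff):
            i, j = int(owner[a]), int(owner[b])
            if i > j:
                i, j = j, i
            if j - i >= MIN_SEQ_SEPARATION:
                residue_pairs.add((i, j))
    elif method == "calpha":
        cutoff = CALPHA_CUTOFF_A if cutoff_A is None else cutoff_A
        tree = cKDTree(structure.coords_A)
        residue_pairs = set()
        for a, b in tree.query_pairs(cutoff):
            i, j = (a, b) if a < b else (b, a)
            if j - i >= MIN_SEQ_SEPARATION:
                residue_pairs.add((i, j))
    else:
        raise ValueError(f"unknown contact method {method!r}")

    pairs = []
    for i, j in sorted(residue_pairs):
        r0 = float(np.linalg.norm(structure.coords_A[i] - structure.coords_A[j]))
        pairs.append((i + 1, j + 1, r0))
    return ContactMap(pairs=pairs, method=method, cutoff_A=cutoff)


@dataclass
class GoHamiltonian:
    """Structure-based potential: bonded terms + native LJ contacts + repulsion.

    All energies in ε, lengths in Å.  Index arrays are 0-based for direct
    array addressing; the public contact map stays 1-based.
    """

    n_beads: int
    bond_idx: np.ndarray  # (nb, 2)
    bond_b0: np.ndarray
    k_bond: float
    angle_idx: np.ndarray  # (na, 3)
    angle_theta0: np.ndarray
    k_angle: float
    dihedral_idx: np.ndarray  # (nd, 4)
    dihedral_phi0: np.ndarray
    k_dihedral_1: float
    k_dihedral_3: float
    contact_idx: np.ndarray  # (nc, 2)
    contact_r0: np.ndarray
    contact_eps: np.ndarray  # per-contact well depth, units of ε
    repulsion_idx: np.ndarray  # (nr, 2) non-contact |i−j| ≥ 3 pairs
    r_repulsive_A: float
    contact_map: ContactMap | None = None


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def build_hamiltonian(
    structure: CGStructure,
    contact_map: ContactMap | None = None,
    k_bond: float = 100.0,
    k_angle: float = 20.0,
    k_dihedral_1: float = 1.0,
    k_dihedral_3: float = 0.5,
    r_repulsive_A: float = 4.0,
    contact_eps_scale: Mapping[str, float] | None = None,
) -> GoHamiltonian:
    """Assemble the Go Hamiltonian from a structure and its contact map.

    Bond lengths, angles and dihedrals take their native values as minima.
    ``contact_eps_scale`` optionally rescales the well depth of contacts
    whose both partners lie inside a named domain (e.g. to soften one
    domain of a toy construct).
    """
    if contact_map is None:
        method = "heavy_atom" if structure.heavy_atoms is not None else "calpha"
        contact_map = build_contact_map(structure, method=method)
    x = structure.coords_A
    n = structure.n_residues

    bond_idx = np.array([(i, i + 1) for i in range(n - 1)], dtype=np.int64)
    bond_b0 = np.linalg.norm(x[1:] - x[:-1], axis=1)

    angle_idx = np.array([(i, i + 1, i + 2) for i in range(n - 2)], dtype=np.int64)
    angle_theta0 = np.array([_angle(x[i], x[i + 1], x[i + 2]) for i in range(n - 2)])

    dihedral_idx = np.array(
        [(i, i + 1, i + 2, i + 3) for i in range(n - 3)], dtype=np.int64
    )
    dihedral_phi0 = np.array(
        [_dihedral(x[i], x[i + 1], x[i + 2], x[i + 3]) for i in range(n - 3)]
    )

    contact_idx = np.array(
        [(i - 1, j - 1) for i, j, _ in contact_map.pairs], dtype=np.int64
    ).reshape(-1, 2)
    contact_r0 = np.array([r0 for _, _, r0 in contact_map.pairs])
    eps = np.ones(len(contact_map.pairs))
    if contact_eps_scale:
        for name, scale in contact_eps_scale.items():
            mask = structure.domain_mask(name)
            for k, (i, j, _) in enumerate(contact_map.pairs):
                if mask[i - 1] and mask[j - 1]:
                    eps[k] = scale

    contact_set = {(int(i), int(j)) for i, j in contact_idx}
    rep_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_SEQ_SEPARATION, n)
        if (i, j) not in contact_set
    ]
    repulsion_idx = np.array(rep_pairs, dtype=np.int64).reshape(-1, 2)

    return GoHamiltonian(
        n_beads=n,
        bond_idx=bond_idx,
        bond_b0=bond_b0,
        k_bond=k_bond,
        angle_idx=angle_idx,
        angle_theta0=angle_theta0,
        k_angle=k_angle,
        dihedral_idx=dihedral_idx,
        dihedral_phi0=dihedral_phi0,
        k_dihedral_1=k_dihedral_1,
        k_dihedral_3=k_dihedral_3,
        contact_idx=contact_idx,
        contact_r0=contact_r0,
        contact_eps=eps,
        repulsion_idx=repulsion_idx,
        r_repulsive_A=r_repulsive_A,
        contact_map=contact_map,
    )


def energy_forces(
    coords: np.ndarray, hamiltonian: GoHamiltonian
) -> tuple[float, np.ndarray]:
    """Total potential energy (ε) and per-bead forces (ε/Å) at ``coords``."""
    from . import _kernels

    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (hamiltonian.n_beads, 3):
        raise ValueError("coordinate array shape mismatch")
    # overlapping beads make the pair terms meaningless
    from scipy.spatial.distance import pdist

    n = hamiltonian.n_beads
    if n > 2:
        d = pdist(coords)
        ii, jj = np.triu_indices(n, k=1)
        nonbonded = jj - ii >= 2
        if (d[nonbonded] < 0.1).any():
            raise ValueError("overlapping beads (separation < 0.1 Å)")
    forces = np.zeros_like(coords)
    energy = _kernels.total_energy_forces(
        coords,
        forces,
        hamiltonian.bond_idx,
        hamiltonian.bond_b0,
        hamiltonian.k_bond,
        hamiltonian.angle_idx,
        hamiltonian.angle_theta0,
        hamiltonian.k_angle,
        hamiltonian.dihedral_idx,
        hamiltonian.dihedral_phi0,
        hamiltonian.k_dihedral_1,
        hamiltonian.k_dihedral_3,
        hamiltonian.contact_idx,
        hamiltonian.contact_r0,
        hamiltonian.contact_eps,
        hamiltonian.repulsion_idx,
        hamiltonian.r_repulsive_A,
    )
    return float(energy), forces


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """Export a contact map as tab-separated (i, j, r0_A) rows."""
    with Path(path).open("w") as fh:
        fh.write(f"#method={cmap.method}\n#cutoff_A={cmap.cutoff_A}\n")
        fh.write("#i\tj\tr0_A\n")
        for i, j, r0 in cmap.pairs:
            fh.write(f"{i}\t{j}\t{r0:.4f}\n")
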
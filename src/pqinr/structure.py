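"""Geometry metrics on macromolecular coordinates.

Supports the interpretation of ring-shaped (toroidal) oligomer
assemblies: optimal rigid-body superposition (Kabsch) with optional
iterative pruning, detection of intermolecular salt bridges, expansion
of crystallographic symmetry into a closed ring assembly, and the axial
pore-radius profile of a ring (largest probe sphere centred on the
symmetry axis that clears all atoms' van der Waals spheres).

File I/O (PDB / mmCIF) goes through gemmi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomModel",
    "RingAssembly",
    "VDW_RADII",
    "superpose_rmsd",
    "find_salt_bridges",
    "pore_profile",
    "assembly_from_symmetry",
]

# Van der Waals radii, Å (Bondi-type consensus values).
VDW_RADII: Mapping[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52,
    "P": 1.80, "S": 1.80, "SE": 1.90,
}
_DEFAULT_VDW = 1.70


@dataclass
class AtomModel:
    """Flat atom table with optional crystal symmetry.

    Arrays are index-aligned; ``coords`` is (n, 3) in Å.  ``structure``
    keeps the underlying gemmi object when the model was read from a
    file (needed for space-group expansion).
    """

    elements: np.ndarray
    names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray
    structure: object = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_file(cls, path) -> "AtomModel":
        """Read a PDB or mmCIF file (format detected by gemmi)."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls.from_gemmi(st)

    @classmethod
    def from_gemmi(cls, st) -> "AtomModel":
        elements, names, res_names, res_ids, chains, coords, occ = \
            [], [], [], [], [], [], []
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name.upper())
                    names.append(atom.name)
                    res_names.append(res.name)
                    res_ids.append(res.seqid.num)
                    chains.append(chain.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    occ.append(atom.occ)
        return cls(
            elements=np.array(elements), names=np.array(names),
            res_names=np.array(res_names), res_ids=np.array(res_ids),
            chains=np.array(chains), coords=np.array(coords, dtype=float),
            occupancies=np.array(occ, dtype=float), structure=st,
        )

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chains == chain

    def ca_coords(self, chain: str) -> np.ndarray:
        mask = self.chain_mask(chain) & (self.names == "CA")
        return self.coords[mask]

    def vdw_radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(el, _DEFAULT_VDW) for el in self.elements])


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares RMSD after optimal rotation of b onto a.

    Returns (rmsd, per-pair distances after superposition).
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    b_fit = bc @ rot
    dists = np.linalg.norm(b_fit - ac, axis=1)
    return float(np.sqrt(np.mean(dists**2))), dists


def superpose_rmsd(coords_a, coords_b,
                   prune_cutoff: float | None = None) -> tuple[float, int]:
    """Optimal rigid-body superposition RMSD of paired coordinate sets.

    With ``prune_cutoff`` set, the worst pair exceeding the cutoff is
    dropped and the superposition repeated until all remaining pairs lie
    within the cutoff (or only 3 pairs remain).  Returns
    ``(rmsd, number of matched pairs)``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    if len(a) < 3:
        raise ValueError("at least 3 paired coordinates are required")
    keep = np.ones(len(a), dtype=bool)
    while True:
        rmsd, dists = _kabsch_rmsd(a[keep], b[keep])
        if prune_cutoff is None:
            return rmsd, int(keep.sum())
        worst = np.argmax(dists)
        if dists[worst] <= prune_cutoff or keep.sum() <= 3:
            return rmsd, int(keep.sum())
        idx = np.flatnonzero(keep)[worst]
        keep[idx] = False


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_BASIC_ATOMS_HIS = {"HIS": ("ND1", "NE2")}


def _charged_atoms(model: AtomModel, chain: str,
                   table: Mapping[str, Sequence[str]]):
    """[(res_name, res_id, coords (k,3))] for charged side-chain atoms."""
    out = []
    mask = model.chain_mask(chain)
    for res_name, atom_names in table.items():
        res_mask = mask & (model.res_names == res_name)
        for res_id in np.unique(model.res_ids[res_mask]):
            sel = res_mask & (model.res_ids == res_id)
            atom_sel = sel & np.isin(model.names, atom_names)
            if not np.any(atom_sel):
                logger.info("skipping %s %s%d: charged side-chain atoms missing",
                            res_name, chain, res_id)
                continue
            out.append((res_name, int(res_id), model.coords[atom_sel]))
    return out


def find_salt_bridges(model: AtomModel, chain_a: str, chain_b: str,
                      cutoff: float = 4.0,
                      include_his: bool = False) -> list[dict]:
    """Intermolecular salt bridges between two chains.

    A bridge is any acidic carboxylate oxygen (Asp/Glu) within ``cutoff``
    of a basic side-chain nitrogen (Lys/Arg; His only when
    ``include_his``), counted once per residue pair and reported
    symmetrically regardless of chain order.
    """
    for chain in (chain_a, chain_b):
        if not np.any(model.chain_mask(chain)):
            raise ValueError(f"chain {chain!r} not present in model")
    basic_table = dict(_BASIC_ATOMS)
    if include_his:
        basic_table.update(_BASIC_ATOMS_HIS)
    bridges: dict[tuple, float] = {}
    for ca, cb in ((chain_a, chain_b), (chain_b, chain_a)):
        for ares, aid, acoords in _charged_atoms(model, ca, _ACIDIC_ATOMS):
            for bres, bid, bcoords in _charged_atoms(model, cb, basic_table):
                d = np.linalg.norm(acoords[:, None, :] - bcoords[None, :, :],
                                   axis=-1).min()
                if d <= cutoff:
                    key = (ares, ca, aid, bres, cb, bid)
                    bridges[key] = min(d, bridges.get(key, np.inf))
    return [
        {"acidic": {"res_name": k[0], "chain": k[1], "res_id": k[2]},
         "basic": {"res_name": k[3], "chain": k[4], "res_id": k[5]},
         "distance": float(v)}
        for k, v in sorted(bridges.items())
    ]


# ---------------------------------------------------------------------------
# Ring assemblies and pore profiles
# ---------------------------------------------------------------------------

@dataclass
class RingAssembly:
    """A closed ring of protomer copies with a defined symmetry axis."""

    coords: np.ndarray            # all atoms of the assembly, (n, 3)
    vdw: np.ndarray               # per-atom van der Waals radii
    protomer_centroids: np.ndarray
    axis_point: np.ndarray
    axis_direction: np.ndarray
    order: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if norm == 0:
            raise ValueError("axis direction must be non-zero")
        self.axis_direction = self.axis_direction / norm
        if self.order < 2:
            raise ValueError("ring order must be >= 2")


def _principal_axis(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal of the best plane through the protomer centroids."""
    center = centroids.mean(axis=0)
    cov = np.cov((centroids - center).T)
    evals, evecs = np.linalg.eigh(cov)
    return center, evecs[:, 0]  # smallest-variance direction


def assembly_from_symmetry(model: AtomModel,
                           operators: Sequence[np.ndarray] | None = None,
                           ) -> RingAssembly:
    """Expand symmetry copies of a model into a closed ring assembly.

    ``operators`` is a list of 4x4 affine matrices applied to the whole
    model (the identity is included automatically if absent).  Without
    explicit operators the model's crystallographic space-group
    operators are applied (crystal symmetry must be present).  A model
    whose chains already form a ring passes through unchanged.

    Copies are deduplicated by centroid, a contact graph is built
    (protomer pairs with centroid separation below twice the median
    nearest-neighbour distance are linked), and the copies are accepted
    as a ring when the graph is a single closed cycle.  The ring axis is
    the normal of the centroid plane.  When no closed ring is found the
    assembly is still returned with ``diagnostics["closed_ring"]=False``.
    """
    protomer_coords: list[np.ndarray] = []
    protomer_vdw: list[np.ndarray] = []

    if operators is not None:
        ops = [np.asarray(op, dtype=float) for op in operators]
        if not any(np.allclose(op, np.eye(4)) for op in ops):
            ops = [np.eye(4)] + ops
        for op in ops:
            xyz = model.coords @ op[:3, :3].T + op[:3, 3]
            protomer_coords.append(xyz)
            protomer_vdw.append(model.vdw_radii())
    elif len(np.unique(model.chains)) >= 2:
        # pre-expanded multi-chain assembly: identity passthrough
        for chain in np.unique(model.chains):
            mask = model.chain_mask(chain)
            protomer_coords.append(model.coords[mask])
            protomer_vdw.append(model.vdw_radii()[mask])
    else:
        import gemmi

        st = model.structure
        if st is None or not st.cell.is_crystal():
            raise ValueError("no crystal symmetry present and no operators given")
        sg = gemmi.SpaceGroup(st.spacegroup_hm)
        frac_m = np.array(st.cell.frac.mat.tolist())
        orth_m = np.array(st.cell.orth.mat.tolist())
        fcoords = model.coords @ frac_m.T
        seen = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            fnew = fcoords @ rot.T + tran
            # wrap the centroid into the unit cell
            c = fnew.mean(axis=0)
            fnew = fnew - np.floor(c)
            xyz = fnew @ orth_m.T
            cen = xyz.mean(axis=0)
            if any(np.linalg.norm(cen - s) < 1.0 for s in seen):
                continue
            seen.append(cen)
            protomer_coords.append(xyz)
            protomer_vdw.append(model.vdw_radii())

    centroids = np.array([c.mean(axis=0) for c in protomer_coords])
    order = len(protomer_coords)
    if order < 2:
        raise ValueError("fewer than 2 protomer copies generated")

    # contact graph on centroid separations; the 1.3x factor separates
    # ring neighbours from next-nearest copies down to square rings
    # (next-nearest/nearest = sqrt(2))
    dists = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    nn = dists.min(axis=1)
    cutoff = 1.3 * np.median(nn)
    adj = dists <= cutoff
    degrees = adj.sum(axis=1)
    closed = bool(np.all(degrees == 2)) and _single_cycle(adj)
    diagnostics = {"closed_ring": closed,
                   "contact_cutoff": float(cutoff),
                   "degrees": degrees.tolist()}
    if not closed:
        logger.warning("symmetry copies do not form a single closed ring; "
                       "returning partial assembly (degrees=%s)",
                       degrees.tolist())
    center, axis = _principal_axis(centroids)
    return RingAssembly(
        coords=np.concatenate(protomer_coords),
        vdw=np.concatenate(protomer_vdw),
        protomer_centroids=centroids,
        axis_point=center, axis_direction=axis, order=order,
        diagnostics=diagnostics,
    )


def _single_cycle(adj: np.ndarray) -> bool:
    """True when an (undirected, degree-2) adjacency is one closed cycle."""
    n = len(adj)
    visited = {0}
    prev, cur = None, 0
    for _ in range(n):
        neigh = [j for j in np.flatnonzero(adj[cur]) if j != prev]
        if not neigh:
            return False
        prev, cur = cur, neigh[0]
        if cur == 0:
            return len(visited) == n
        visited.add(cur)
    return False


def pore_profile(assembly: RingAssembly, step: float = 1.0) -> dict:
    """Largest-probe radius along the ring axis.

    At each axial station the pore radius is the largest probe sphere
    centred on the axis that clears every atom's van der Waals sphere:
    min over atoms of (distance to probe centre - vdw radius).  Stations
    span the axial extent of the assembly.  Returns a dict with ``z``
    (axial coordinate relative to the centroid plane), ``radius``,
    ``min_pore_diameter`` and ``max_outer_diameter``.
    """
    if assembly.coords.size == 0:
        raise ValueError("empty assembly")
    if step <= 0:
        raise ValueError("step must be > 0")
    rel = assembly.coords - assembly.axis_point
    z_atoms = rel @ assembly.axis_direction
    radial = np.linalg.norm(rel - z_atoms[:, None] * assembly.axis_direction,
                            axis=1)
    z_lo, z_hi = z_atoms.min(), z_atoms.max()
    z = np.arange(z_lo, z_hi + step, step)
    centres = (assembly.axis_point[None, :]
               + z[:, None] * assembly.axis_direction[None, :])
    d = np.linalg.norm(centres[:, None, :] - assembly.coords[None, :, :],
                       axis=-1)
    radius = (d - assembly.vdw[None, :]).min(axis=1)
    outer = float(2.0 * (radial + assembly.vdw).max())
    return {
        "z": z,
        "radius": radius,
        "min_pore_diameter": float(2.0 * radius.min()),
        "max_outer_diameter": outer,
    }
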
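"""Structure-level comparisons between homologous protein models.

Contact maps are Cα–Cα proximity sets (default cutoff 8.0 Å, inclusive,
sequence neighbors retained).  Two maps are compared after matching their
residues through a global (Needleman–Wunsch) sequence alignment, yielding
unique-to-A / unique-to-B / common partitions that satisfy
|unique_x| + |common| = total_x by construction.  Superposition uses the
Kabsch least-squares rotation; structural clustering applies
average-linkage hierarchical clustering to the pairwise CA-RMSD matrix.
Interaction networks collect every residue with any atom within a radius
of a focal residue's side chain, and hydrogen bonds are detected with a
geometric donor–acceptor criterion (3.0 Å donor–acceptor distance and 20°
donor-angle deviation, the common visualization-tool default), with amide
hydrogens reconstructed when the model carries none.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .errors import ComparisonError, InputError, StructureError
from .io_core import BACKBONE_ATOMS, StructureModel
from .seq_evolution import global_align

Contact = tuple[int, int]


@dataclass
class ContactMap:
    model_id: str
    contacts: frozenset[Contact]
    cutoff: float
    n_residues: int
    atom_selector: str = "CA"

    @property
    def total(self) -> int:
        return len(self.contacts)


@dataclass
class ContactDiff:
    pair: tuple[str, str]
    unique_a: frozenset[Contact]
    unique_b: frozenset[Contact]
    common: frozenset[Contact]  # in A's residue numbering
    residue_hotspots: list[tuple[int, int]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {"total_a": len(self.unique_a) + len(self.common),
                "total_b": len(self.unique_b) + len(self.common),
                "unique_a": len(self.unique_a),
                "unique_b": len(self.unique_b),
                "common": len(self.common)}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_aligned: int
    degenerate: bool = False


@dataclass
class InteractionNetwork:
    model_id: str
    focal_residue: int
    radius: float
    partners: list[tuple[int, float]]  # (residue index, minimal distance)
    focal_atoms: str = "side_chain"
    gly_fallback: bool = False

    @property
    def partner_set(self) -> set[int]:
        return {p for p, _ in self.partners}


@dataclass
class HBond:
    donor_residue: int
    donor_atom: str
    acceptor_residue: int
    acceptor_atom: str
    distance: float  # donor–acceptor heavy-atom distance, Å
    angle: float | None  # H-D-A donor angle in degrees; None if no hydrogen
    heavy_only: bool = False


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    method: str = "average"
    criterion: str = "maxclust"

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def groups(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for mid, lab in self.labels.items():
            out.setdefault(lab, set()).add(mid)
        return out


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def build_contact_map(model: StructureModel, cutoff: float = 8.0) -> ContactMap:
    """Residue pairs (i<j) whose CA atoms are within ``cutoff`` Å (inclusive)."""
    ca = model.ca_coords()
    d = cdist(ca, ca)
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    contacts = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))
    return ContactMap(model_id=model.model_id, contacts=contacts,
                      cutoff=cutoff, n_residues=model.residue_count)


def diff_contact_maps(map_a: ContactMap, map_b: ContactMap,
                      seq_a: str, seq_b: str) -> ContactDiff:
    """Compare two contact maps after global sequence alignment.

    Contacts involving residues with no counterpart in the other sequence
    are counted unique.  The partition identities
    |unique_a| + |common| = total_a (and likewise for b) always hold.
    """
    if abs(map_a.cutoff - map_b.cutoff) > 1e-9:
        raise ComparisonError(
            f"cutoff mismatch: {map_a.cutoff} vs {map_b.cutoff}")
    ga, gb = global_align(seq_a, seq_b, "protein")
    a_to_b: dict[int, int] = {}
    b_to_a: dict[int, int] = {}
    ia = ib = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            a_to_b[ia + 1] = ib + 1
            b_to_a[ib + 1] = ia + 1
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1

    def mapped(contact: Contact, mapping: dict[int, int]) -> Contact | None:
        i, j = contact
        if i in mapping and j in mapping:
            mi, mj = mapping[i], mapping[j]
            return (mi, mj) if mi < mj else (mj, mi)
        return None

    common_a = frozenset(c for c in map_a.contacts
                         if (m := mapped(c, a_to_b)) is not None
                         and m in map_b.contacts)
    unique_a = map_a.contacts - common_a
    common_b = frozenset(c for c in map_b.contacts
                         if (m := mapped(c, b_to_a)) is not None
                         and m in map_a.contacts)
    unique_b = map_b.contacts - common_b

    hot: Counter[int] = Counter()
    for i, j in unique_a:
        hot[i] += 1
        hot[j] += 1
    for i, j in unique_b:
        for r in (i, j):
            hot[b_to_a.get(r, -r)] += 1  # unmapped b-residues keyed negative
    hotspots = sorted(hot.items(), key=lambda kv: (-kv[1], kv[0]))
    return ContactDiff(pair=(map_a.model_id, map_b.model_id),
                       unique_a=unique_a, unique_b=unique_b, common=common_a,
                       residue_hotspots=hotspots)


# ---------------------------------------------------------------------------
# superposition and clustering
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_a: np.ndarray,
                     coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (Kabsch, SVD form,
    reflection-corrected).  RMSD is over the matched points."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("coordinate arrays must both be (n, 3)")
    if a.shape[0] < 3:
        raise InputError("need at least 3 matched points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    degenerate = s[1] < 1e-8 * max(s[0], 1.0)
    b_fit = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((b_fit - a0) ** 2, axis=1))))
    translation = ca - rot @ cb
    return SuperpositionResult(rotation=rot, translation=translation,
                               rmsd=rmsd, n_aligned=a.shape[0],
                               degenerate=bool(degenerate))


def matched_ca_coords(model_a: StructureModel, model_b: StructureModel
                      ) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinate pairs for residues matched by global sequence alignment."""
    ga, gb = global_align(model_a.sequence, model_b.sequence, "protein")
    ca_a, ca_b = model_a.ca_coords(), model_b.ca_coords()
    rows_a, rows_b = [], []
    ia = ib = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            rows_a.append(ca_a[ia])
            rows_b.append(ca_b[ib])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return np.asarray(rows_a), np.asarray(rows_b)


def pairwise_rmsd_matrix(models: list[StructureModel]) -> np.ndarray:
    n = len(models)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matched_ca_coords(models[i], models[j])
            d[i, j] = d[j, i] = kabsch_superpose(a, b).rmsd
    return d


def cluster_structures(models: list[StructureModel],
                       k: int | None = None) -> ClusterAssignment:
    """Average-linkage hierarchical clustering of pairwise CA RMSDs.

    Cut at ``k`` clusters when given, otherwise at the largest gap between
    successive linkage heights.
    """
    if len(models) < 2:
        raise InputError("need at least 2 models to cluster")
    d = pairwise_rmsd_matrix(models)
    z = linkage(squareform(d, checks=False), method="average")
    if k is None:
        heights = z[:, 2]
        if np.allclose(heights, 0.0):
            k = 1
        else:
            gaps = np.diff(np.concatenate([[0.0], heights]))
            # cutting below the largest merge gap leaves that many clusters
            k = len(models) - int(np.argmax(gaps))
    if k <= 1 or np.allclose(d, 0.0):
        labels = {m.model_id: 1 for m in models}
        return ClusterAssignment(labels=labels, criterion="gap")
    flat = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels={m.model_id: int(c) for m, c in zip(models, flat)},
        criterion="maxclust" if k else "gap")


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def interaction_network(model: StructureModel, focal_residue: int,
                        radius: float = 5.0,
                        focal_atoms: str = "side_chain") -> InteractionNetwork:
    """Residues with any atom within ``radius`` Å (inclusive) of the focal
    residue's chosen atoms.  ``focal_atoms`` is "side_chain" (default; falls
    back to CA for glycine, flagged), "all", or "CA".
    """
    indices = model.residue_indices
    if focal_residue not in indices:
        raise InputError(f"focal residue {focal_residue} not in model")
    res_atoms = model.residue_atoms(focal_residue)
    gly_fallback = False
    if focal_atoms == "side_chain":
        focal = [a for a in res_atoms if a.atom_name not in BACKBONE_ATOMS
                 and not a.atom_name.startswith("H")]
        if not focal:
            focal = [a for a in res_atoms if a.atom_name == "CA"]
            gly_fallback = True
    elif focal_atoms == "CA":
        focal = [a for a in res_atoms if a.atom_name == "CA"]
    elif focal_atoms == "all":
        focal = list(res_atoms)
    else:
        raise InputError(f"unknown focal_atoms selector {focal_atoms!r}")
    fc = np.array([[a.x, a.y, a.z] for a in focal])

    partners: list[tuple[int, float]] = []
    for ridx in indices:
        if ridx == focal_residue:
            continue
        other = model.residue_atoms(ridx)
        oc = np.array([[a.x, a.y, a.z] for a in other])
        dmin = float(cdist(fc, oc).min())
        if dmin <= radius:
            partners.append((ridx, dmin))
    return InteractionNetwork(model_id=model.model_id,
                              focal_residue=focal_residue, radius=radius,
                              partners=partners, focal_atoms=focal_atoms,
                              gly_fallback=gly_fallback)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

# Side-chain heavy atoms that can donate a hydrogen (full-atom models).
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
# Acceptor heavy atoms: backbone O plus side-chain oxygens / imidazole N.
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}


def detect_hbonds(model: StructureModel, d_cutoff: float = 3.0,
                  angle_cutoff: float = 20.0,
                  heavy_extra: float = 0.2) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    Donor–acceptor heavy-atom distance must be ≤ ``d_cutoff`` Å and the
    donor angle (between D→H and D→A) ≤ ``angle_cutoff`` degrees.  Backbone
    amide hydrogens are taken from the file when present, otherwise
    reconstructed geometrically.  Donors whose hydrogen cannot be placed
    (side-chain heavy atoms in hydrogen-free models) use the distance
    criterion alone at ``d_cutoff + heavy_extra`` Å and are flagged.
    """
    indices = model.residue_indices
    has_h = any(a.atom_name in ("H", "HN") for a in model.atoms)
    recon_h: dict[int, np.ndarray] = {}
    if not has_h:
        # lenient reconstruction: H only where C(prev), N and CA all exist
        for k, ridx in enumerate(indices):
            if k == 0:
                continue
            c_prev = model.atom(indices[k - 1], "C")
            n_at = model.atom(ridx, "N")
            ca_at = model.atom(ridx, "CA")
            if c_prev is None or n_at is None or ca_at is None:
                continue
            u = n_at.coords - c_prev.coords
            v = n_at.coords - ca_at.coords
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            w = u + v
            recon_h[ridx] = n_at.coords + 1.01 * w / np.linalg.norm(w)

    donors: list[tuple[int, str, np.ndarray, np.ndarray | None]] = []
    acceptors: list[tuple[int, str, np.ndarray]] = []
    for ridx in indices:
        rname = model.residue_name(ridx)
        for a in model.residue_atoms(ridx):
            if a.atom_name == "N" and rname != "PRO":
                h = None
                if has_h:
                    ha = model.atom(ridx, "H") or model.atom(ridx, "HN")
                    h = ha.coords if ha is not None else None
                else:
                    h = recon_h.get(ridx)
                donors.append((ridx, "N", a.coords, h))
            elif a.atom_name in _SIDECHAIN_DONORS.get(rname, ()):
                h = None  # side-chain H placement not attempted
                donors.append((ridx, a.atom_name, a.coords, h))
            if a.atom_name == "O" or a.atom_name in _SIDECHAIN_ACCEPTORS.get(rname, ()):
                acceptors.append((ridx, a.atom_name, a.coords))

    bonds: list[HBond] = []
    for dres, dname, dxyz, hxyz in donors:
        for ares, aname, axyz in acceptors:
            if dres == ares:
                continue
            dist = float(np.linalg.norm(axyz - dxyz))
            if hxyz is not None:
                if dist > d_cutoff:
                    continue
                v1 = hxyz - dxyz
                v2 = axyz - dxyz
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang > angle_cutoff:
                    continue
                bonds.append(HBond(dres, dname, ares, aname, dist, ang))
            else:
                if dist > d_cutoff + heavy_extra:
                    continue
                bonds.append(HBond(dres, dname, ares, aname, dist, None,
                                   heavy_only=True))
    bonds.sort(key=lambda b: (b.donor_residue, b.acceptor_residue,
                              b.donor_atom, b.acceptor_atom))
    return bonds


def hbonds_near_residue(model: StructureModel, focal_residue: int,
                        radius: float = 5.0, **hbond_kwargs) -> list[HBond]:
    """Hydrogen bonds with either partner residue having ≥ 1 atom within
    ``radius`` Å of any atom of the focal residue."""
    all_bonds = detect_hbonds(model, **hbond_kwargs)
    focal_atoms = model.residue_atoms(focal_residue)
    if not focal_atoms:
        raise InputError(f"focal residue {focal_residue} not in model")
    fc = np.array([[a.x, a.y, a.z] for a in focal_atoms])
    near: set[int] = {focal_residue}
    for ridx in model.residue_indices:
        if ridx == focal_residue:
            continue
        oc = np.array([[a.x, a.y, a.z] for a in model.residue_atoms(ridx)])
        if cdist(fc, oc).min() <= radius:
            near.add(ridx)
    return [b for b in all_bonds
            if b.donor_residue in near or b.acceptor_residue in near]


def hbond_table_rows(model: StructureModel, bonds: list[HBond]) -> list[str]:
    """Human-readable "Donor-res – Acceptor-res" pair strings."""
    from .io_core import THREE_TO_ONE  # noqa: F401 (kept for symmetry)
    rows = []
    for b in bonds:
        dn = model.residue_name(b.donor_residue).capitalize()
        an = model.residue_name(b.acceptor_residue).capitalize()
        rows.append(f"{dn}-{b.donor_residue} – {an}-{b.acceptor_residue}")
    return rows
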
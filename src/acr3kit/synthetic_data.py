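"""Synthetic fixtures with known ground truth.

Two generators cover the pipeline's two input kinds:

* :func:`generate_helix_bundle` builds α-helical bundle models (ideal
  backbone geometry, antiparallel helices on a ring, single pseudo-atom
  side chains) emulating the ten-transmembrane-helix architecture of
  Acr3-family transporters.  Point mutations and Gaussian coordinate
  noise create variant families whose differing positions and cluster
  structure are known by construction.
* :func:`simulate_codon_family` evolves coding sequences from a common
  root under a proposal/acceptance codon process with a controllable
  non-synonymous acceptance probability ω, giving families whose dN/dS
  regime is known (the defaults target the strong-purifying regime,
  ω ≈ 0.1–0.15, typical of essential transporter genes).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io_core import AtomRecord, ONE_TO_THREE, SequenceRecord, StructureModel

# Distance (Å) from CA to the single side-chain pseudo-atom, roughly the
# distance to the side-chain centroid; glycine has no side-chain atom.
SIDECHAIN_PSEUDO_DIST = {
    "A": 1.50, "R": 3.50, "N": 2.25, "D": 2.20, "C": 1.80,
    "Q": 2.75, "E": 2.70, "G": 0.00, "H": 2.75, "I": 2.30,
    "L": 2.30, "K": 3.00, "M": 2.65, "F": 2.95, "P": 1.85,
    "S": 1.70, "T": 1.90, "V": 1.95, "W": 3.50, "Y": 3.30,
}

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Backbone internal coordinates (Engh–Huber-like ideal values).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
# Helix dihedrals: canonical right-handed α-helix (O(i)…N(i+4) ≈ 2.94 Å).
PHI_HELIX, PSI_HELIX = -60.0, -47.0
PHI_EXT, PSI_EXT = 180.0, 180.0


@dataclass(frozen=True)
class BundleSpec:
    n_helices: int = 10
    residues_per_helix: int = 25
    loop_length: int = 4
    ring_radius: float = 12.0
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1:
            raise ParameterError("n_helices must be >= 1")
        if self.residues_per_helix < 5:
            raise ParameterError("residues_per_helix must be >= 5")
        if self.loop_length < 0:
            raise ParameterError("loop_length must be >= 0")
        if self.n_helices > 1 and self.ring_radius <= 6.0:
            raise ParameterError("ring_radius must exceed the helix packing radius (6 Å)")

    @property
    def total_residues(self) -> int:
        return (self.n_helices * self.residues_per_helix
                + (self.n_helices - 1) * self.loop_length)


@dataclass(frozen=True)
class CodonSimSpec:
    root: str
    n_taxa: int = 11
    branch_length: float = 0.3  # expected accepted substitutions per codon
    omega: float = 0.13
    kappa: float = 1.0  # transition/transversion proposal bias
    seed: int = 0

    def __post_init__(self):
        if len(self.root) % 3 != 0 or not self.root:
            raise ParameterError("root length must be a positive multiple of 3")
        root = self.root.upper()
        for i in range(0, len(root), 3):
            if root[i:i + 3] in STOP_CODONS:
                raise ParameterError(f"root contains stop codon at codon {i // 3 + 1}")
        if set(root) - set("ACGT"):
            raise ParameterError("root must be a DNA sequence over ACGT")
        if self.n_taxa < 1:
            raise ParameterError("n_taxa must be >= 1")
        if self.branch_length < 0:
            raise ParameterError("branch_length must be >= 0")
        if self.omega < 0:
            raise ParameterError("omega must be >= 0")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom D with |CD|=bond, ∠BCD=angle, τ(ABCD)=torsion."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> np.ndarray:
    """(n_res, 3, 3) array of N, CA, C coordinates for a homogeneous chain."""
    coords = np.zeros((n_res, 3, 3))
    # seed triad for residue 0
    coords[0, 0] = [0.0, 0.0, 0.0]                       # N
    coords[0, 1] = [_B_N_CA, 0.0, 0.0]                   # CA
    coords[0, 2] = _place_atom(np.array([0.0, 1.0, 0.0]),
                               coords[0, 0], coords[0, 1],
                               _B_CA_C, _A_N_CA_C, 180.0)  # C
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, 180.0)  # ω trans
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        coords[i] = [n_i, ca_i, c_i]
    return coords


def _carbonyl_oxygens(bb: np.ndarray) -> np.ndarray:
    """Place O anti to the next residue's N in the sp2 carbonyl plane."""
    n_res = bb.shape[0]
    oxy = np.zeros((n_res, 3))
    for i in range(n_res):
        n_i, ca_i, c_i = bb[i]
        if i + 1 < n_res:
            ref = bb[i + 1, 0]  # next N
            oxy[i] = _place_atom(ref, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            oxy[i] = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, PSI_HELIX + 180.0)
    return oxy


def _cb_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Unit vector from CA toward the ideal Cβ position (tetrahedral)."""
    u = n - ca
    v = c - ca
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bisector = -(u + v)
    perp = np.cross(v, u)
    d = bisector / np.linalg.norm(bisector) * np.cos(np.radians(54.0)) \
        + perp / np.linalg.norm(perp) * np.sin(np.radians(54.0))
    return d / np.linalg.norm(d)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient from first to last point
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180° flip about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


_DEFAULT_HELIX_AA = "AILVFMWAILVFMTSAILVFMWAIL"  # hydrophobic-rich
_DEFAULT_LOOP_AA = "GKRS"


def _default_sequence(spec: BundleSpec, rng: np.random.Generator) -> str:
    parts = []
    for h in range(spec.n_helices):
        core = "".join(rng.choice(list("AILVFMTSWG"), size=spec.residues_per_helix))
        parts.append(core)
        if h < spec.n_helices - 1:
            parts.append("".join(rng.choice(list("GKRSDNE"), size=spec.loop_length)))
    return "".join(parts)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_helix_bundle(spec: BundleSpec) -> StructureModel:
    """Build an α-helical bundle model with backbone N, CA, C, O and a single
    side-chain pseudo-atom (named CB) per non-glycine residue.

    Helices use ideal α-helix dihedrals, so the i→i+4 backbone hydrogen-bond
    geometry holds by construction; helices alternate direction (antiparallel)
    and sit on a ring of ``ring_radius``; loops are extended connectors placed
    along the line between consecutive helix ends.  Deterministic given seed.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence if spec.sequence is not None else _default_sequence(spec, rng)
    if len(seq) != spec.total_residues:
        raise ParameterError(
            f"sequence length {len(seq)} != expected {spec.total_residues}")
    for aa in seq:
        if aa not in SIDECHAIN_PSEUDO_DIST:
            raise ParameterError(f"non-standard residue {aa!r} in sequence")

    m = spec.residues_per_helix
    helix_bb = _build_backbone(m, PHI_HELIX, PSI_HELIX)
    axis = _principal_axis(helix_bb[:, 1, :])

    placed: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # per-residue N,CA,C
    prev_end: np.ndarray | None = None
    for h in range(spec.n_helices):
        up = h % 2 == 0
        target = np.array([0.0, 0.0, 1.0]) if up else np.array([0.0, 0.0, -1.0])
        rot = _rotation_between(axis, target)
        bb = helix_bb @ rot.T
        theta = 2.0 * np.pi * h / max(spec.n_helices, 2)
        center = np.array([spec.ring_radius * np.cos(theta),
                           spec.ring_radius * np.sin(theta), 0.0])
        bb = bb - bb[:, 1, :].mean(axis=0) + center
        if prev_end is not None and spec.loop_length > 0:
            start = bb[0, 1]
            for k in range(1, spec.loop_length + 1):
                t = k / (spec.loop_length + 1)
                ca = prev_end + t * (start - prev_end)
                u = (start - prev_end)
                u /= np.linalg.norm(u)
                perp = np.cross(u, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(u, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                placed.append((ca - 1.2 * u + 0.5 * perp, ca, ca + 1.2 * u + 0.5 * perp))
        placed.extend([(bb[i, 0], bb[i, 1], bb[i, 2]) for i in range(m)])
        prev_end = bb[-1, 1]

    bb_all = np.array(placed)  # (n, 3, 3)
    oxy = _carbonyl_oxygens(bb_all)

    atoms: list[AtomRecord] = []
    serial = 0
    for i, aa in enumerate(seq):
        resname = ONE_TO_THREE[aa]
        n_i, ca_i, c_i = bb_all[i]
        entries = [("N", n_i, "N"), ("CA", ca_i, "C"), ("C", c_i, "C"),
                   ("O", oxy[i], "O")]
        dist = SIDECHAIN_PSEUDO_DIST[aa]
        if dist > 0:
            cb = ca_i + dist * _cb_direction(n_i, ca_i, c_i)
            entries.append(("CB", cb, "C"))
        for name, xyz, elem in entries:
            serial += 1
            atoms.append(AtomRecord(serial=serial, atom_name=name,
                                    residue_name=resname, chain_id="A",
                                    residue_index=i + 1,
                                    x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
                                    element=elem, original_index=i + 1))
    return StructureModel(model_id=f"bundle_seed{spec.seed}", atoms=atoms)


def apply_mutations(model: StructureModel,
                    mutations: Sequence[tuple[int, str]]) -> StructureModel:
    """Return a copy of ``model`` with residue identities changed at the given
    1-based positions.  The backbone is untouched; the side-chain pseudo-atom
    is re-placed at the new residue's characteristic distance.
    """
    n = model.residue_count
    for pos, aa in mutations:
        if not 1 <= pos <= n:
            raise ParameterError(f"mutation position {pos} outside 1..{n}")
        if aa not in SIDECHAIN_PSEUDO_DIST:
            raise ParameterError(f"non-standard replacement residue {aa!r}")
    mut_map = {pos: aa for pos, aa in mutations}
    atoms: list[AtomRecord] = []
    serial = 0
    for ridx in model.residue_indices:
        res_atoms = model.residue_atoms(ridx)
        if ridx not in mut_map:
            for a in res_atoms:
                serial += 1
                atoms.append(replace(a, serial=serial))
            continue
        new_aa = mut_map[ridx]
        new_name = ONE_TO_THREE[new_aa]
        n_a = next((a for a in res_atoms if a.atom_name == "N"), None)
        ca_a = next(a for a in res_atoms if a.atom_name == "CA")
        c_a = next((a for a in res_atoms if a.atom_name == "C"), None)
        for a in res_atoms:
            if a.atom_name == "CB":
                continue
            serial += 1
            atoms.append(replace(a, serial=serial, residue_name=new_name))
        dist = SIDECHAIN_PSEUDO_DIST[new_aa]
        if dist > 0 and n_a is not None and c_a is not None:
            cb = ca_a.coords + dist * _cb_direction(n_a.coords, ca_a.coords, c_a.coords)
            serial += 1
            atoms.append(AtomRecord(serial=serial, atom_name="CB",
                                    residue_name=new_name, chain_id=ca_a.chain_id,
                                    residue_index=ridx,
                                    x=float(cb[0]), y=float(cb[1]), z=float(cb[2]),
                                    element="C", original_index=ca_a.original_index))
    return StructureModel(model_id=model.model_id + "_mut", atoms=atoms)


def perturb_structure(model: StructureModel, sigma: float,
                      seed: int = 0) -> StructureModel:
    """Add i.i.d. Gaussian displacement (std ``sigma`` Å) to every atom."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(model.atoms), 3)) if sigma > 0 \
        else np.zeros((len(model.atoms), 3))
    atoms = [replace(a, x=a.x + float(d[0]), y=a.y + float(d[1]), z=a.z + float(d[2]))
             for a, d in zip(model.atoms, noise)]
    return StructureModel(model_id=model.model_id + f"_p{seed}", atoms=atoms)


# ---------------------------------------------------------------------------
# codon simulator
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


_NUCS = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def simulate_codon_family(spec: CodonSimSpec) -> list[SequenceRecord]:
    """Evolve ``n_taxa`` sequences independently from the root.

    Each taxon receives a Poisson(branch_length × n_codons) number of accepted
    substitutions.  A substitution is proposed as a random point mutation
    (transition-biased with weight ``kappa``); proposals creating a stop codon
    are always rejected, non-synonymous proposals are accepted with probability
    proportional to ω, synonymous ones with probability proportional to 1 (for
    ω > 1 the roles invert so acceptance stays a probability).
    """
    rng = np.random.default_rng(spec.seed)
    table = _codon_table()
    root = spec.root.upper()
    n_codons = len(root) // 3
    p_non = min(1.0, spec.omega)
    p_syn = min(1.0, 1.0 / spec.omega) if spec.omega > 1 else 1.0

    records: list[SequenceRecord] = []
    for t in range(spec.n_taxa):
        seq = list(root)
        target = rng.poisson(spec.branch_length * n_codons)
        accepted = 0
        guard = 0
        max_attempts = 200 * (target + 10) * 10
        while accepted < target:
            guard += 1
            if guard > max_attempts:
                break  # ω=0 with no synonymous options, or similar dead end
            pos = int(rng.integers(len(seq)))
            old = seq[pos]
            # transition-biased proposal among the 3 alternatives
            alts = [n for n in _NUCS if n != old]
            weights = np.array([spec.kappa if n == _TRANSITION[old] else 1.0
                                for n in alts])
            new = alts[int(rng.choice(3, p=weights / weights.sum()))]
            cstart = pos - pos % 3
            old_codon = "".join(seq[cstart:cstart + 3])
            new_codon = old_codon[:pos - cstart] + new + old_codon[pos - cstart + 1:]
            if new_codon in STOP_CODONS:
                continue
            synonymous = table[new_codon] == table[old_codon]
            p_accept = p_syn if synonymous else p_non
            if p_accept < 1.0 and rng.random() >= p_accept:
                continue
            seq[pos] = new
            accepted += 1
        records.append(SequenceRecord(id=f"taxon_{t + 1:03d}", residues="".join(seq)))
    return records


def random_coding_sequence(n_codons: int, seed: int = 0) -> str:
    """A random stop-free CDS of ``n_codons`` codons (uniform over sense codons)."""
    rng = np.random.default_rng(seed)
    table = _codon_table()
    sense = sorted(c for c in table if c not in STOP_CODONS)
    return "".join(sense[int(i)] for i in rng.integers(len(sense), size=n_codons))
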
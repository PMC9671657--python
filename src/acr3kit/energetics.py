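"""Per-residue binding-energy decomposition (simplified MM-GBSA).

The binding energy of a focal residue A against its contact environment B
(all residues with any atom within a radius, default 5 Å) is

    ΔG_bind = G_TOTAL(AB) − G_TOTAL(A) − G_TOTAL(B)

where G_TOTAL = H_MM + G_solv, H_MM is the non-bonded molecular-mechanics
energy (Coulomb + Lennard-Jones 12-6), and G_solv = G_polar + G_nonpolar
combines a pairwise generalized-Born (Still) polar term with a γ·SASA
non-polar term.  Everything is evaluated on a single fixed conformation
(single-snapshot approximation): bonded terms cancel in the difference and
are omitted, and effective Born radii are the intrinsic atomic GB radii
(no descreening integral).  Parameters come from a small bundled table
(backbone atoms per-atom, side chains as a single united pseudo-atom
carrying the residue's formal charge offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ClashError, InputError, ParameterError
from .io_core import StructureModel

COULOMB_K = 332.0636  # kcal·Å/(mol·e²)
GB_K = 166.0          # ½ × Coulomb constant, Still convention

FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}


@dataclass
class ParameterSet:
    table: pd.DataFrame
    dielectric_in: float = 1.0
    dielectric_out: float = 78.5
    surface_tension: float = 0.0072  # kcal/mol/Å²
    probe_radius: float = 1.4
    version: str = "1"

    def lookup(self, residue: str, atom: str) -> dict | None:
        hit = self.table[(self.table.residue == residue) & (self.table.atom == atom)]
        if hit.empty:
            return None
        return hit.iloc[0].to_dict()


def load_default_parameters(**overrides) -> ParameterSet:
    """Load the bundled simplified force-field table."""
    with resources.files("acr3kit.params").joinpath("ff_simple.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return ParameterSet(table=table, **overrides)


@dataclass
class ParameterizedModel:
    model: StructureModel
    params: ParameterSet
    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_rmin: np.ndarray
    gb_radius: np.ndarray
    vdw_radius: np.ndarray
    coords: np.ndarray
    residue_of_atom: np.ndarray  # residue index per atom

    def atom_indices_of(self, residues: set[int]) -> np.ndarray:
        mask = np.isin(self.residue_of_atom, sorted(residues))
        return np.nonzero(mask)[0]


@dataclass
class EnergyTerms:
    h_mm: float
    g_polar: float
    g_nonpolar: float

    @property
    def g_solv(self) -> float:
        return self.g_polar + self.g_nonpolar

    @property
    def g_total(self) -> float:
        return self.h_mm + self.g_solv


@dataclass
class EnergyDecomposition:
    focal_residue: int
    environment: set[int]
    terms_ab: EnergyTerms
    terms_a: EnergyTerms
    terms_b: EnergyTerms
    empty_environment: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def delta_g_bind(self) -> float:
        if self.empty_environment:
            return 0.0
        return self.terms_ab.g_total - self.terms_a.g_total - self.terms_b.g_total


# ---------------------------------------------------------------------------

def assign_parameters(model: StructureModel,
                      params: ParameterSet | None = None) -> ParameterizedModel:
    """Attach partial charge, LJ, GB-radius and vdW-radius arrays to a model.

    Per-residue charges sum to the residue's formal charge.  Hydrogens get
    zero charge and token LJ parameters; side-chain heavy atoms beyond the
    first (full-atom models) get zero charge and generic carbon parameters,
    so the united side-chain charge stays on the first side-chain atom.
    """
    if params is None:
        params = load_default_parameters()
    n = len(model.atoms)
    charges = np.zeros(n)
    eps = np.zeros(n)
    rmin = np.zeros(n)
    gb = np.zeros(n)
    vdw = np.zeros(n)
    res_of = np.zeros(n, dtype=int)
    known_res = set(params.table.residue)
    sidechain_charged: set[int] = set()
    for k, a in enumerate(model.atoms):
        res_of[k] = a.residue_index
        if a.residue_name not in known_res:
            raise ParameterError(f"no parameters for residue {a.residue_name!r}")
        row = params.lookup(a.residue_name, a.atom_name)
        if row is not None:
            charges[k] = row["charge"]
            eps[k], rmin[k] = row["lj_epsilon"], row["lj_rmin"]
            gb[k], vdw[k] = row["gb_radius"], row["vdw_radius"]
            if a.atom_name == "CB":
                sidechain_charged.add(a.residue_index)
            continue
        if a.atom_name.startswith("H") or a.element == "H":
            charges[k], eps[k], rmin[k], gb[k], vdw[k] = 0.0, 0.0157, 0.6, 1.2, 1.2
            continue
        # other side-chain heavy atom: generic carbon, charge carried elsewhere
        first_sc = a.residue_index not in sidechain_charged
        q = FORMAL_CHARGE.get(a.residue_name, 0) + 0.20 if first_sc else 0.0
        if first_sc:
            sidechain_charged.add(a.residue_index)
        charges[k], eps[k], rmin[k], gb[k], vdw[k] = q, 0.109, 1.908, 1.7, 1.7
    # residues with missing atoms (partial models): park the residual charge
    # on CA so every residue still sums to its formal charge
    for ridx in model.residue_indices:
        mask = res_of == ridx
        want = FORMAL_CHARGE.get(model.residue_name(ridx), 0)
        residual = want - charges[mask].sum()
        if abs(residual) > 1e-9:
            for k, a in enumerate(model.atoms):
                if a.residue_index == ridx and a.atom_name == "CA":
                    charges[k] += residual
                    break
    pm = ParameterizedModel(model=model, params=params, charges=charges,
                            lj_epsilon=eps, lj_rmin=rmin, gb_radius=gb,
                            vdw_radius=vdw, coords=model.coords(),
                            residue_of_atom=res_of)
    _check_charge_sums(pm)
    return pm


def _check_charge_sums(pm: ParameterizedModel) -> None:
    for ridx in pm.model.residue_indices:
        mask = pm.residue_of_atom == ridx
        total = pm.charges[mask].sum()
        want = FORMAL_CHARGE.get(pm.model.residue_name(ridx), 0)
        if abs(total - want) > 1e-6:
            raise ParameterError(
                f"residue {ridx} charge sum {total:.4f} != formal {want}")


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                 n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's sphere (radius + probe) is sampled with a deterministic
    Fibonacci point set; points inside any neighbor's expanded sphere are
    buried.  Returns (per-atom SASA, total SASA) in Å².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise InputError("SASA of an empty atom set is undefined")
    if (radii <= 0).any():
        raise ParameterError("all radii must be positive")
    sphere = _fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    rmax = expanded.max()
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i],
                                                      expanded[i] + rmax)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d = np.linalg.norm(pts[:, None, :] - coords[nb][None, :, :], axis=2)
            # points exactly on a coincident neighbor's surface belong to the
            # lower-index atom, so duplicated spheres are not double-counted
            thresh = expanded[nb] + np.where(nb < i, 1e-9, -1e-9)
            exposed = (d >= thresh[None, :]).all(axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        out[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out, float(out.sum())


# ---------------------------------------------------------------------------
# MM and GB terms
# ---------------------------------------------------------------------------

def _exclusion_pairs(pm: ParameterizedModel, idx: np.ndarray) -> set[tuple[int, int]]:
    """Pairs excluded from the non-bonded sum: same residue, and the 1-2
    bonded C(i)–N(i+1) backbone pair across adjacent residues."""
    excl: set[tuple[int, int]] = set()
    names = [pm.model.atoms[k].atom_name for k in idx]
    res = pm.residue_of_atom[idx]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if res[a] == res[b]:
                excl.add((a, b))
            elif abs(res[a] - res[b]) == 1:
                lo, hi = (a, b) if res[a] < res[b] else (b, a)
                if names[lo] == "C" and names[hi] == "N":
                    excl.add((a, b))
    return excl


def mm_energy(pm: ParameterizedModel, residues: set[int] | None = None) -> float:
    """Non-bonded molecular-mechanics energy of an atom group (kcal/mol):
    Coulomb q_i q_j · 332.0636/(ε_in·r) plus Lennard-Jones 12-6, excluding
    intra-residue pairs and peptide-bond C–N pairs."""
    idx = (np.arange(len(pm.model.atoms)) if residues is None
           else pm.atom_indices_of(residues))
    coords = pm.coords[idx]
    q = pm.charges[idx]
    eps = pm.lj_epsilon[idx]
    rmin = pm.lj_rmin[idx]
    excl = _exclusion_pairs(pm, idx)
    e = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if (a, b) in excl:
                continue
            r = float(np.linalg.norm(coords[a] - coords[b]))
            if r < 0.1:
                raise ClashError(f"atoms {idx[a]} and {idx[b]} at {r:.3f} Å")
            e += COULOMB_K * q[a] * q[b] / (pm.params.dielectric_in * r)
            e_ij = np.sqrt(eps[a] * eps[b])
            r_ij = rmin[a] + rmin[b]
            if e_ij > 0:
                sr6 = (r_ij / r) ** 6
                e += e_ij * (sr6 * sr6 - 2.0 * sr6)
    return e


def gb_energy(pm: ParameterizedModel, residues: set[int] | None = None) -> float:
    """Pairwise generalized-Born polar solvation energy (Still formula):

        G = −166·(1/ε_in − 1/ε_out)·Σ_i Σ_j q_i q_j / f_GB(r_ij)
        f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j)));  f_GB(i,i) = R_i

    with intrinsic radii used directly as effective Born radii."""
    idx = (np.arange(len(pm.model.atoms)) if residues is None
           else pm.atom_indices_of(residues))
    q = pm.charges[idx]
    radii = pm.gb_radius[idx]
    if (radii <= 0).any():
        raise ParameterError("non-positive GB radius")
    coords = pm.coords[idx]
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    qq = q[:, None] * q[None, :]
    pref = GB_K * (1.0 / pm.params.dielectric_in - 1.0 / pm.params.dielectric_out)
    return float(-pref * np.sum(qq / f))


def energy_terms(pm: ParameterizedModel, residues: set[int] | None = None,
                 include_solvation: bool = True,
                 n_sasa_points: int = 960) -> EnergyTerms:
    h_mm = mm_energy(pm, residues)
    if not include_solvation:
        return EnergyTerms(h_mm=h_mm, g_polar=0.0, g_nonpolar=0.0)
    g_polar = gb_energy(pm, residues)
    idx = (np.arange(len(pm.model.atoms)) if residues is None
           else pm.atom_indices_of(residues))
    _, total_sasa = compute_sasa(pm.coords[idx], pm.vdw_radius[idx],
                                 probe=pm.params.probe_radius,
                                 n_points=n_sasa_points)
    return EnergyTerms(h_mm=h_mm, g_polar=g_polar,
                       g_nonpolar=pm.params.surface_tension * total_sasa)


def binding_energy(pm: ParameterizedModel, focal_residue: int,
                   radius: float = 5.0, include_solvation: bool = True,
                   n_sasa_points: int = 960) -> EnergyDecomposition:
    """ΔG_bind of a focal residue A against its ≤ radius environment B.

    G_TOTAL is evaluated for AB, A and B on the fixed coordinates and the
    difference reported; an empty environment returns ΔG_bind = 0 with a
    warning note.
    """
    indices = pm.model.residue_indices
    if focal_residue not in indices:
        raise InputError(f"focal residue {focal_residue} not in model")
    focal_idx = pm.atom_indices_of({focal_residue})
    fc = pm.coords[focal_idx]
    env: set[int] = set()
    for ridx in indices:
        if ridx == focal_residue:
            continue
        oc = pm.coords[pm.atom_indices_of({ridx})]
        dmin = np.sqrt(((fc[:, None, :] - oc[None, :, :]) ** 2).sum(axis=2)).min()
        if dmin <= radius:
            env.add(ridx)
    if not env:
        zero = EnergyTerms(0.0, 0.0, 0.0)
        return EnergyDecomposition(focal_residue=focal_residue, environment=set(),
                                   terms_ab=zero, terms_a=zero, terms_b=zero,
                                   empty_environment=True,
                                   notes=["empty environment; delta_g_bind = 0"])
    kw = dict(include_solvation=include_solvation, n_sasa_points=n_sasa_points)
    terms_ab = energy_terms(pm, env | {focal_residue}, **kw)
    terms_a = energy_terms(pm, {focal_residue}, **kw)
    terms_b = energy_terms(pm, env, **kw)
    return EnergyDecomposition(focal_residue=focal_residue, environment=env,
                               terms_ab=terms_ab, terms_a=terms_a, terms_b=terms_b)


def binding_energy_table(pm: ParameterizedModel, focal_residues: list[int],
                         radius: float = 5.0, **kwargs) -> pd.DataFrame:
    rows = []
    for fr in focal_residues:
        dec = binding_energy(pm, fr, radius=radius, **kwargs)
        rows.append({
            "residue": fr,
            "residue_name": pm.model.residue_name(fr),
            "n_environment": len(dec.environment),
            "G_TOTAL_AB": dec.terms_ab.g_total,
            "G_TOTAL_A": dec.terms_a.g_total,
            "G_TOTAL_B": dec.terms_b.g_total,
            "delta_G_bind": dec.delta_g_bind,
        })
    return pd.DataFrame(rows)
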
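"""Contact maps, superposition, clustering, networks and hydrogen bonds,
checked against brute-force implementations."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from acr3kit import struct_compare as sc
from acr3kit.errors import ComparisonError, InputError
from acr3kit.io_core import AtomRecord, BACKBONE_ATOMS, StructureModel
from acr3kit.synthetic_data import (BundleSpec, apply_mutations,
                                    generate_helix_bundle, perturb_structure)
from conftest import random_structure_pair


def _two_residue_model(distance):
    atoms = []
    for i, x in enumerate((0.0, distance), start=1):
        atoms.append(AtomRecord(serial=i, atom_name="CA", residue_name="ALA",
                                chain_id="A", residue_index=i,
                                x=x, y=0.0, z=0.0, element="C",
                                original_index=i))
    return StructureModel(model_id=f"pair{distance}", atoms=atoms)


class TestContactMap:
    @pytest.mark.parametrize("distance,expected", [(7.9, 1), (8.0, 1), (8.1, 0)])
    def test_cutoff_boundary_inclusive(self, distance, expected):
        cm = sc.build_contact_map(_two_residue_model(distance), cutoff=8.0)
        assert cm.total == expected

    def test_matches_brute_force_scan(self, small_bundle):
        cm = sc.build_contact_map(small_bundle, cutoff=8.0)
        ca = small_bundle.ca_coords()
        expected = set()
        for i in range(len(ca)):
            for j in range(i + 1, len(ca)):
                if np.linalg.norm(ca[i] - ca[j]) <= 8.0:
                    expected.add((i + 1, j + 1))
        assert cm.contacts == expected


class TestContactDiff:
    def test_map_vs_itself_all_common(self, small_bundle):
        cm = sc.build_contact_map(small_bundle)
        d = sc.diff_contact_maps(cm, cm, small_bundle.sequence,
                                 small_bundle.sequence)
        assert len(d.unique_a) == len(d.unique_b) == 0
        assert len(d.common) == cm.total

    def test_partition_identity_on_random_pairs(self):
        for seed in range(10):
            a, b = random_structure_pair(seed + 1)
            ma, mb = sc.build_contact_map(a), sc.build_contact_map(b)
            d = sc.diff_contact_maps(ma, mb, a.sequence, b.sequence)
            c = d.counts
            assert c["unique_a"] + c["common"] == ma.total
            assert c["unique_b"] + c["common"] == mb.total

    def test_diff_is_mirror_symmetric(self):
        a, b = random_structure_pair(99)
        ma, mb = sc.build_contact_map(a), sc.build_contact_map(b)
        d1 = sc.diff_contact_maps(ma, mb, a.sequence, b.sequence)
        d2 = sc.diff_contact_maps(mb, ma, b.sequence, a.sequence)
        assert d1.unique_a == d2.unique_b
        assert d1.unique_b == d2.unique_a
        assert len(d1.common) == len(d2.common)

    def test_cutoff_mismatch_rejected(self, small_bundle):
        m1 = sc.build_contact_map(small_bundle, cutoff=8.0)
        m2 = sc.build_contact_map(small_bundle, cutoff=7.0)
        with pytest.raises(ComparisonError):
            sc.diff_contact_maps(m1, m2, small_bundle.sequence,
                                 small_bundle.sequence)


def _quaternion_rmsd(a, b):
    """Independent oracle: optimal superposition via Horn's quaternion method."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e = float((a0 ** 2).sum() + (b0 ** 2).sum()) - 2.0 * lam
    return np.sqrt(max(e, 0.0) / a.shape[0])


class TestKabsch:
    def test_identical_coordinates_rmsd_zero(self, small_bundle):
        ca = small_bundle.ca_coords()
        assert sc.kabsch_superpose(ca, ca).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, small_bundle, rng):
        ca = small_bundle.ca_coords()
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = ca @ q.T + rng.normal(size=3) * 10
        res = sc.kabsch_superpose(ca, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            a = rng.normal(size=(n, 3)) * 5
            b = a + rng.normal(size=(n, 3)) * rng.uniform(0.05, 2.0)
            assert sc.kabsch_superpose(a, b).rmsd == \
                pytest.approx(_quaternion_rmsd(a, b), abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            sc.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestClustering:
    def test_identical_copies_form_one_cluster(self, small_bundle):
        models = [perturb_structure(small_bundle, 0.0, seed=i) for i in range(3)]
        for i, m in enumerate(models):
            m.model_id = f"copy{i}"
        assert sc.cluster_structures(models).n_clusters == 1

    def test_two_perturbation_groups_recovered(self):
        spec1 = BundleSpec(n_helices=2, residues_per_helix=14, loop_length=3,
                           ring_radius=9.0, seed=1)
        parent1 = generate_helix_bundle(spec1)
        # second parent: same fold, substantially displaced helices
        spec2 = BundleSpec(n_helices=2, residues_per_helix=14, loop_length=3,
                           ring_radius=13.0, seed=1)
        parent2 = generate_helix_bundle(spec2)
        models = []
        for g, parent in enumerate((parent1, parent2)):
            for i in range(3):
                m = perturb_structure(parent, sigma=0.2, seed=g * 10 + i)
                m.model_id = f"g{g}_{i}"
                models.append(m)
        groups = sc.cluster_structures(models, k=2).groups()
        got = {frozenset(v) for v in groups.values()}
        want = {frozenset(f"g0_{i}" for i in range(3)),
                frozenset(f"g1_{i}" for i in range(3))}
        assert got == want


class TestInteractionNetwork:
    def test_radius_boundary(self):
        # focal CB at origin-ish; place another residue at controlled distance
        def model_with_gap(gap):
            atoms = [
                AtomRecord(1, "N", "ALA", "A", 1, 0.0, 1.4, 0.0, "N", 1),
                AtomRecord(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", 1),
                AtomRecord(3, "C", "ALA", "A", 1, 1.4, 0.0, 0.0, "C", 1),
                AtomRecord(4, "O", "ALA", "A", 1, 2.0, 1.0, 0.0, "O", 1),
                AtomRecord(5, "CB", "ALA", "A", 1, 0.0, 0.0, 1.5, "C", 1),
                AtomRecord(6, "CA", "GLY", "A", 2, 0.0, 0.0, 1.5 + gap, "C", 2),
            ]
            return StructureModel(model_id="gap", atoms=atoms)

        assert sc.interaction_network(model_with_gap(5.1), 1).partners == []
        net = sc.interaction_network(model_with_gap(4.9), 1)
        assert net.partner_set == {2}
        assert net.partners[0][1] == pytest.approx(4.9)

    def test_matches_brute_force_all_atom_scan(self, small_bundle):
        focal = 10
        net = sc.interaction_network(small_bundle, focal, radius=5.0)
        focal_atoms = [a for a in small_bundle.residue_atoms(focal)
                       if a.atom_name not in BACKBONE_ATOMS]
        fc = np.array([[a.x, a.y, a.z] for a in focal_atoms])
        expected = set()
        for ridx in small_bundle.residue_indices:
            if ridx == focal:
                continue
            oc = np.array([[a.x, a.y, a.z]
                           for a in small_bundle.residue_atoms(ridx)])
            if cdist(fc, oc).min() <= 5.0:
                expected.add(ridx)
        assert net.partner_set == expected

    def test_glycine_falls_back_to_ca_flagged(self):
        model = apply_mutations(generate_helix_bundle(
            BundleSpec(n_helices=1, residues_per_helix=10, loop_length=0,
                       ring_radius=10.0, seed=2)), [(5, "G")])
        net = sc.interaction_network(model, 5)
        assert net.gly_fallback

    def test_sequence_neighbors_included(self, single_helix):
        net = sc.interaction_network(single_helix, 8, radius=5.0)
        assert {7, 9} <= net.partner_set


class TestHBonds:
    def test_textbook_linear_geometry_detected(self):
        # donor N-H ... O acceptor, H...O 2.0 Å, perfectly linear
        atoms = [
            AtomRecord(1, "CA", "ALA", "A", 1, -1.2, 1.0, 0.0, "C", 1),
            AtomRecord(2, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N", 1),
            AtomRecord(3, "H", "ALA", "A", 1, 1.01, 0.0, 0.0, "H", 1),
            AtomRecord(4, "C", "ALA", "A", 1, -1.5, -0.8, 0.0, "C", 1),
            AtomRecord(5, "O", "ALA", "A", 1, -1.5, -2.0, 0.0, "O", 1),
            AtomRecord(6, "CA", "ALA", "A", 2, 4.2, 1.0, 0.0, "C", 2),
            AtomRecord(7, "N", "ALA", "A", 2, 5.0, 2.0, 0.0, "N", 2),
            AtomRecord(8, "C", "ALA", "A", 2, 4.0, -0.5, 0.0, "C", 2),
            AtomRecord(9, "O", "ALA", "A", 2, 3.01, 0.0, 0.0, "O", 2),
        ]
        model = StructureModel(model_id="hb", atoms=atoms)
        bonds = sc.detect_hbonds(model, d_cutoff=3.1)
        assert any(b.donor_residue == 1 and b.acceptor_residue == 2
                   and b.donor_atom == "N" for b in bonds)

    def test_ideal_helix_bonds_are_i_to_i_minus_4(self, single_helix):
        bonds = sc.detect_hbonds(single_helix)
        backbone = [b for b in bonds if b.donor_atom == "N"
                    and b.acceptor_atom == "O"]
        assert backbone
        assert all(b.donor_residue - b.acceptor_residue == 4 for b in backbone)

    def test_far_apart_atoms_no_bond(self):
        atoms = [
            AtomRecord(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", 1),
            AtomRecord(2, "O", "ALA", "A", 1, 1.2, 0.0, 0.0, "O", 1),
            AtomRecord(3, "CA", "ALA", "A", 2, 5.0, 0.0, 0.0, "C", 2),
            AtomRecord(4, "N", "ALA", "A", 2, 6.2, 0.0, 0.0, "N", 2),
        ]
        model = StructureModel(model_id="far", atoms=atoms)
        assert sc.detect_hbonds(model) == []

    def test_near_residue_output_is_subset(self, small_bundle):
        all_bonds = {(b.donor_residue, b.acceptor_residue, b.donor_atom,
                      b.acceptor_atom) for b in sc.detect_hbonds(small_bundle)}
        near = sc.hbonds_near_residue(small_bundle, 10, radius=5.0)
        near_keys = {(b.donor_residue, b.acceptor_residue, b.donor_atom,
                      b.acceptor_atom) for b in near}
        assert near_keys <= all_bonds

    def test_isolated_focal_residue_has_empty_neighborhood(self):
        atoms = [
            AtomRecord(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", 1),
            AtomRecord(2, "CA", "ALA", "A", 2, 50.0, 0.0, 0.0, "C", 2),
        ]
        model = StructureModel(model_id="iso", atoms=atoms)
        assert sc.hbonds_near_residue(model, 2, radius=5.0) == []
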
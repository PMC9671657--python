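"""Sequence-evolution statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from acr3kit import seq_evolution as se
from acr3kit.errors import (DegenerateInputError, DimensionError, InputError,
                            SaturationError)
from acr3kit.io_core import SequenceRecord
from acr3kit.synthetic_data import (STOP_CODONS, _codon_table,
                                    random_coding_sequence,
                                    simulate_codon_family, CodonSimSpec)


# ---------------------------------------------------------------------------
# independent NG86 oracle (pathway enumeration written from the definition,
# shares no code with the implementation)
# ---------------------------------------------------------------------------

def _oracle_syn_sites(codon, table):
    aa = table[codon]
    total = 0.0
    for pos, base in enumerate(codon):
        syn = 0
        for alt in "ACGT":
            if alt == base:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1:]
            if mutated not in STOP_CODONS and table[mutated] == aa:
                syn += 1
        total += syn / 3.0
    return total


def _oracle_path_steps(c_from, c_to, table):
    """Classify one substitution step as ('s'|'n')."""
    if c_from in STOP_CODONS or c_to in STOP_CODONS:
        return "n"
    return "s" if table[c_from] == table[c_to] else "n"


def _oracle_diffs(c1, c2, table):
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur, sd, nd, hits_stop = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                hits_stop = True
            if _oracle_path_steps(cur, nxt, table) == "s":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, hits_stop))
    good = [(s, n) for s, n, stop in results if not stop]
    if not good:
        good = [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in good) / len(good),
            sum(n for _, n in good) / len(good))


def oracle_ng86(a, b):
    table = _codon_table()
    S = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        n_codons += 1
        S += (_oracle_syn_sites(ca, table) + _oracle_syn_sites(cb, table)) / 2
        sd, nd = _oracle_diffs(ca, cb, table)
        Sd += sd
        Nd += nd
    N = 3 * n_codons - S
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(pN), jc(pS)


class TestNeiGojobori:
    def test_identical_sequences_have_zero_rates(self):
        seq = random_coding_sequence(50, seed=1)
        st = se.nei_gojobori(seq, seq)
        assert st.dN == 0.0 and st.dS == 0.0 and st.ratio is None

    def test_purely_synonymous_changes_give_ratio_zero(self):
        a = "TTA" * 9 + "TTG"
        b = "TTA" * 10
        st = se.nei_gojobori(a, b)
        assert st.dN == 0.0
        assert st.dS > 0.0
        assert st.ratio == 0.0

    def test_matches_pathway_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            root = random_coding_sequence(30, seed=int(rng.integers(2**31)))
            fam = simulate_codon_family(CodonSimSpec(
                root=root, n_taxa=1, branch_length=0.5, omega=0.5,
                seed=int(rng.integers(2**31))))
            a, b = root, fam[0].residues
            try:
                st = se.nei_gojobori(a, b)
            except (SaturationError, DegenerateInputError):
                continue
            dn_o, ds_o = oracle_ng86(a, b)
            assert st.dN == pytest.approx(dn_o, abs=1e-12)
            assert st.dS == pytest.approx(ds_o, abs=1e-12)

    def test_symmetric_in_its_arguments(self):
        a = random_coding_sequence(60, seed=3)
        fam = simulate_codon_family(CodonSimSpec(root=a, n_taxa=1,
                                                 branch_length=0.4, seed=4))
        b = fam[0].residues
        s1, s2 = se.nei_gojobori(a, b), se.nei_gojobori(b, a)
        assert s1.dN == pytest.approx(s2.dN, abs=1e-15)
        assert s1.dS == pytest.approx(s2.dS, abs=1e-15)

    def test_gapped_codons_skipped_pairwise(self):
        a = "ATG---GCT"
        b = "ATGAAAGCT"
        st = se.nei_gojobori(a, b)
        assert st.dN == 0.0 and st.dS == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            se.nei_gojobori("TTA", "TTG")  # 1 codon: pS = 1.5 >= 3/4


class TestBackTranslation:
    def test_single_gap_expansion(self):
        aln = se.Alignment(records=[SequenceRecord("x", "M-A"),
                                    SequenceRecord("y", "MKA")])
        cds = {"x": SequenceRecord("x", "ATGGCT"),
               "y": SequenceRecord("y", "ATGAAAGCT")}
        out = se.back_translate_alignment(aln, cds)
        assert out.records[0].residues == "ATG---GCT"
        assert out.records[1].residues == "ATGAAAGCT"

    def test_round_trip_recovers_cds(self):
        root = random_coding_sequence(40, seed=8)
        fam = simulate_codon_family(CodonSimSpec(root=root, n_taxa=4,
                                                 branch_length=0.2, seed=8))
        prot = [SequenceRecord(r.id, se.translate(r.residues)) for r in fam]
        aln = se.Alignment(records=prot)
        codon_aln = se.back_translate_alignment(aln, {r.id: r for r in fam})
        for orig, back in zip(fam, codon_aln.records):
            assert back.residues.replace("-", "") == orig.residues

    def test_translation_mismatch_is_reported_with_position(self):
        aln = se.Alignment(records=[SequenceRecord("x", "MA"),
                                    SequenceRecord("y", "MA")])
        cds = {"x": SequenceRecord("x", "ATGTGT"),  # TGT = Cys, not Ala
               "y": SequenceRecord("y", "ATGGCT")}
        with pytest.raises(InputError, match="position 2"):
            se.back_translate_alignment(aln, cds)


class TestIdentity:
    def test_identical_sequences_100_percent(self):
        r = SequenceRecord("a", "MKTAYIAK")
        assert se.pairwise_identity(r, r) == 100.0

    def test_single_mismatch_no_gaps(self):
        a = SequenceRecord("a", "ACGT")
        b = SequenceRecord("b", "ACGA")
        assert se.pairwise_identity(a, b, "nucleotide") == 75.0

    def test_matrix_symmetric_zero_diagonal(self, rng):
        records = [SequenceRecord(f"s{i}", "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40)))
            for i in range(4)]
        dm = se.identity_matrix(records)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)


class TestClassicalMds:
    def test_345_triangle_embeds_exactly(self):
        dm = se.DistanceMatrix(labels=["a", "b", "c"],
                               values=np.array([[0, 3, 4], [3, 0, 5],
                                                [4, 5, 0]], float))
        coords = se.classical_mds(dm, 2).values
        np.testing.assert_allclose(squareform(pdist(coords)), dm.values,
                                   atol=1e-9)

    def test_recovers_planar_points_up_to_rigid_motion(self, rng):
        pts = rng.normal(size=(8, 2)) * 5
        d = squareform(pdist(pts))
        dm = se.DistanceMatrix(labels=[f"p{i}" for i in range(8)], values=d)
        coords = se.classical_mds(dm, 2).values
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-8

    def test_rank_deficient_request_raises_with_usable_rank(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])  # collinear
        d = squareform(pdist(pts))
        dm = se.DistanceMatrix(labels=list("abcd"), values=d)
        with pytest.raises(DimensionError) as err:
            se.classical_mds(dm, 3)
        assert err.value.usable_rank == 1

    def test_sign_convention_deterministic(self):
        dm = se.DistanceMatrix(labels=list("abc"),
                               values=np.array([[0, 3, 4], [3, 0, 5],
                                                [4, 5, 0]], float))
        c1 = se.classical_mds(dm, 2).values
        c2 = se.classical_mds(dm, 2).values
        np.testing.assert_array_equal(c1, c2)
        first_nonzero = c1[np.abs(c1[:, 0]) > 1e-12, 0][0]
        assert first_nonzero > 0


def _tree_distance(newick_dists, a, b):
    return newick_dists[(a, b)] if (a, b) in newick_dists else newick_dists[(b, a)]


class TestNeighborJoining:
    ADDITIVE = se.DistanceMatrix(
        labels=list("ABCD"),
        values=np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                         [5, 6, 0, 7], [6, 7, 7, 0]], float))

    def test_additive_matrix_recovers_generating_split(self):
        tree = se.nj_tree(self.ADDITIVE)
        assert tree.has_split(["A", "B"])
        assert tree.has_split(["C", "D"])
        assert not tree.has_split(["A", "C"])

    def test_three_taxa_solves_exactly(self):
        dm = se.DistanceMatrix(labels=list("XYZ"),
                               values=np.array([[0, 5, 9], [5, 0, 10],
                                                [9, 10, 0]], float))
        tree = se.nj_tree(dm)
        # leaf branch lengths from the 3-equation system: x=2, y=3, z=7
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths == pytest.approx({"X": 2.0, "Y": 3.0, "Z": 7.0})

    def test_random_additive_matrices_recover_topology(self, rng):
        # random caterpillar tree on 6 taxa; four-point-condition oracle
        for trial in range(10):
            labels = [f"t{i}" for i in range(6)]
            # build random additive distances from a fixed topology
            # ((t0,t1),(t2,t3),(t4,t5)) star of cherries
            bl = rng.uniform(0.5, 3.0, size=9)
            d = np.zeros((6, 6))
            leaf_edge = bl[:6]
            inner = {0: bl[6], 1: bl[7], 2: bl[8]}  # cherry -> center
            for i in range(6):
                for j in range(i + 1, 6):
                    ci, cj = i // 2, j // 2
                    if ci == cj:
                        d[i, j] = leaf_edge[i] + leaf_edge[j]
                    else:
                        d[i, j] = (leaf_edge[i] + inner[ci]
                                   + inner[cj] + leaf_edge[j])
                    d[j, i] = d[i, j]
            tree = se.nj_tree(se.DistanceMatrix(labels=labels, values=d))
            for pair in (["t0", "t1"], ["t2", "t3"], ["t4", "t5"]):
                assert tree.has_split(pair)

    def test_newick_is_parseable_by_biopython(self):
        from io import StringIO
        from Bio import Phylo
        tree = se.nj_tree(self.ADDITIVE)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert {t.name for t in parsed.get_terminals()} == set("ABCD")


class TestSideChainClasses:
    @pytest.mark.parametrize("aa,cls", [
        ("D", "negative"), ("E", "negative"),
        ("R", "positive"), ("H", "positive"), ("K", "positive"),
        ("S", "polar-uncharged"), ("Q", "polar-uncharged"),
        ("A", "hydrophobic"), ("W", "hydrophobic"),
        ("C", "special"), ("G", "special"), ("P", "special"),
    ])
    def test_class_assignments(self, aa, cls):
        assert se.classify_side_chain(aa) == cls

    def test_partition_is_total_and_disjoint(self):
        seen = {}
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            seen[aa] = se.classify_side_chain(aa)
        assert len(seen) == 20
        classes = set(seen.values())
        assert classes == set(se.SIDE_CHAIN_CLASSES)

    def test_non_standard_rejected(self):
        with pytest.raises(InputError):
            se.classify_side_chain("B")


class TestVariablePositions:
    def test_identical_sequences_empty_table(self):
        aln = se.Alignment(records=[SequenceRecord("a", "ACD"),
                                    SequenceRecord("b", "ACD")])
        assert se.variable_positions(aln).positions == []

    def test_single_variable_column_classified(self):
        aln = se.Alignment(records=[SequenceRecord("a", "ACD"),
                                    SequenceRecord("b", "ACE")])
        table = se.variable_positions(aln)
        assert table.positions == [3]
        assert table.rows.iloc[0]["classes"] == "negative"
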
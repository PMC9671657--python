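"""Sequence-level comparative analyses.

Covers the gene/protein side of the pipeline: back-translation of protein
alignments to codon alignments, Nei–Gojobori (1986) dN/dS with Jukes–Cantor
correction, global-alignment percent identity, identity-derived distance
matrices, classical (Torgerson) MDS ordination, Saitou–Nei neighbor-joining
trees, and variable-position (non-conserved residue) tables with the 5-way
side-chain classification (negative / positive / polar-uncharged /
hydrophobic / special).

dN/dS here is the counting estimator: per-codon synonymous site fractions
averaged over both sequences, observed differences averaged with equal
weight over all minimal substitution pathways, and d = −(3/4)·ln(1 − 4p/3)
applied to both proportions.  ω = dN/dS < 1 indicates purifying selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (DegenerateInputError, DimensionError, InputError,
                     SaturationError)
from .io_core import SequenceRecord
from .synthetic_data import STOP_CODONS, _codon_table

GAP = "-"

SIDE_CHAIN_CLASSES = {
    "negative": set("DE"),
    "positive": set("RHK"),
    "polar-uncharged": set("STNQ"),
    "hydrophobic": set("AVILMFYW"),
    "special": set("CGP"),
}
_CLASS_OF = {aa: cls for cls, aas in SIDE_CHAIN_CLASSES.items() for aa in aas}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    records: list[SequenceRecord]
    alphabet: str = "protein"  # or "nucleotide"

    def __post_init__(self):
        if len(self.records) < 2:
            raise InputError("an alignment needs at least 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise InputError(f"unequal gapped lengths in alignment: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def column(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class CodonAlignment(Alignment):
    alphabet: str = "nucleotide"

    def __post_init__(self):
        super().__post_init__()
        if self.length % 3 != 0:
            raise InputError("codon alignment length not divisible by 3")


@dataclass
class SelectionStats:
    pair: tuple[str, str]
    dN: float
    dS: float
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float

    @property
    def ratio(self) -> float | None:
        """dN/dS; None when dS = 0 (undefined)."""
        if self.dS <= 0:
            return None
        return self.dN / self.dS


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.isfinite(v).all():
            raise InputError("non-finite entries in distance matrix")
        if not np.allclose(v, v.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InputError("distance matrix diagonal is not zero")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class VariantTable:
    """Non-conserved alignment columns: 1-based position, per-record residue,
    side-chain classes present, and optional topological location (E/M/C)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def positions(self) -> list[int]:
        return [] if self.rows.empty else self.rows["position"].tolist()

    def to_tsv_frame(self) -> pd.DataFrame:
        return self.rows


class _Node:
    __slots__ = ("name", "children", "min_leaf")

    def __init__(self, name: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.name = name
        self.children = children or []
        if name is not None:
            self.min_leaf = name
        else:
            self.min_leaf = min(c.min_leaf for c, _ in self.children)

    def leaves(self) -> set[str]:
        if self.name is not None:
            return {self.name}
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return out

    def newick(self) -> str:
        if self.name is not None:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree from neighbor-joining, serializable to Newick."""

    root: _Node
    clamped_branches: list[tuple[str, str]] = field(default_factory=list)

    @property
    def leaf_names(self) -> set[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        return self.root.newick() + ";"

    def splits(self) -> list[frozenset[str]]:
        """Leaf sets on the child side of every internal edge."""
        out: list[frozenset[str]] = []

        def walk(node: _Node):
            for child, _ in node.children:
                if child.name is None:
                    out.append(frozenset(child.leaves()))
                walk(child)

        walk(self.root)
        return out

    def has_split(self, labels: Sequence[str]) -> bool:
        """True if some edge separates exactly ``labels`` from the rest
        (i.e. the set is monophyletic in the unrooted sense)."""
        want = frozenset(labels)
        all_leaves = frozenset(self.leaf_names)
        if want == all_leaves or len(want) <= 1:
            return True
        complement = all_leaves - want
        for split in self.splits():
            if split == want or split == complement:
                return True
        # trivial splits around the (arbitrary) root's direct leaf children
        for child, _ in self.root.children:
            if child.name is not None and frozenset([child.name]) in (want, complement):
                return True
        return False


# ---------------------------------------------------------------------------
# pairwise alignment (shared by identity and contact-map matching)
# ---------------------------------------------------------------------------

def _make_aligner(alphabet: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_align(a: str, b: str, alphabet: str = "protein") -> tuple[str, str]:
    """Needleman–Wunsch global alignment with affine gaps; returns the two
    gapped strings of the highest-scoring alignment (first in tie order)."""
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    aligner = _make_aligner(alphabet)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def back_translate_alignment(protein_aln: Alignment,
                             cds: Mapping[str, SequenceRecord]) -> CodonAlignment:
    """Expand a gapped protein alignment to the corresponding codon alignment.

    Each amino-acid column becomes its source codon, each ``-`` becomes
    ``---``.  A trailing stop codon on the CDS is stripped; internal stops
    and translation mismatches are errors.
    """
    table = _codon_table()
    out: list[SequenceRecord] = []
    for rec in protein_aln.records:
        if rec.id not in cds:
            raise InputError(f"no CDS provided for record {rec.id!r}")
        dna = cds[rec.id].residues.upper().replace("U", "T")
        protein = rec.residues.replace(GAP, "")
        if len(dna) == 3 * len(protein) + 3 and dna[-3:] in STOP_CODONS:
            dna = dna[:-3]
        if len(dna) != 3 * len(protein):
            raise InputError(
                f"{rec.id}: CDS length {len(dna)} does not match "
                f"3 x protein length ({3 * len(protein)})")
        codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
        for i, (codon, aa) in enumerate(zip(codons, protein), start=1):
            if codon in STOP_CODONS:
                raise InputError(f"{rec.id}: internal stop codon at codon {i}")
            if table[codon] != aa:
                raise InputError(
                    f"{rec.id}: codon {codon} at position {i} translates to "
                    f"{table[codon]}, protein has {aa}")
        it = iter(codons)
        gapped = "".join("---" if ch == GAP else next(it) for ch in rec.residues)
        out.append(SequenceRecord(id=rec.id, residues=gapped,
                                  description=rec.description))
    return CodonAlignment(records=out)


def translate(dna: str) -> str:
    table = _codon_table()
    return "".join(table["".join(dna[i:i + 3])]
                   for i in range(0, len(dna) - len(dna) % 3, 3))


# --- Nei–Gojobori (1986) ----------------------------------------------------

@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (changes to stops count as
    non-synonymous, i.e. not synonymous)."""
    table = _codon_table()
    aa = table[codon]
    s = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOP_CODONS and table[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two codons,
    averaged with equal weight over all minimal substitution pathways.
    Pathways passing through a stop codon are excluded when any stop-free
    pathway exists."""
    table = _codon_table()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[float, float, bool]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            if nxt in STOP_CODONS or cur in STOP_CODONS \
                    or table.get(cur) != table.get(nxt):
                nd += 1.0
            else:
                sd += 1.0
            cur = nxt
        pathways.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in pathways if not stop]
    use = clean if clean else [(s, n) for s, n, _ in pathways]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences p={p:.4f} >= 3/4; distance undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def nei_gojobori(a: str, b: str, pair: tuple[str, str] = ("a", "b")) -> SelectionStats:
    """NG86 dN and dS for two gap-aligned coding sequences.

    Codon pairs where either sequence is gapped are skipped pairwise.
    Raises :class:`SaturationError` when a proportion reaches 3/4 and
    :class:`DegenerateInputError` when no synonymous sites remain.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise InputError("sequences must have equal (aligned) length")
    if len(a) % 3 != 0:
        raise InputError("aligned length must be divisible by 3")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if GAP in ca or GAP in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise InputError(f"stop codon at aligned codon {i // 3 + 1}")
        n_codons += 1
        s_sites += 0.5 * (_syn_sites(ca) + _syn_sites(cb))
        sd, nd = _pathway_counts(ca, cb)
        s_diff += sd
        n_diff += nd
    if n_codons == 0:
        raise InputError("no comparable (gap-free) codons")
    n_sites = 3.0 * n_codons - s_sites
    if s_sites <= 0:
        raise DegenerateInputError("zero synonymous sites; dS undefined")
    pS = s_diff / s_sites
    pN = n_diff / n_sites
    return SelectionStats(pair=pair, dN=_jukes_cantor(pN), dS=_jukes_cantor(pS),
                          n_sites=n_sites, s_sites=s_sites,
                          n_diffs=n_diff, s_diffs=s_diff)


# --- identity / distances ---------------------------------------------------

def pairwise_identity(a: SequenceRecord, b: SequenceRecord,
                      alphabet: str = "protein") -> float:
    """Percent identity from a global alignment: matches / aligned columns
    (dual-gap columns excluded) × 100."""
    ga, gb = global_align(a.residues, b.residues, alphabet)
    matches = cols = 0
    for x, y in zip(ga, gb):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y:
            matches += 1
    return 100.0 * matches / cols


def identity_matrix(records: Sequence[SequenceRecord],
                    alphabet: str = "protein") -> DistanceMatrix:
    """All-vs-all identity stored as distance = 100 − identity%."""
    if len(records) < 2:
        raise InputError("need at least 2 records")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(records[i], records[j], alphabet)
            d[i, j] = d[j, i] = 100.0 - ident
    return DistanceMatrix(labels=[r.id for r in records], values=d,
                          metric_name="100-identity")


# --- classical MDS ----------------------------------------------------------

def classical_mds(dm: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Torgerson classical scaling of a distance matrix into k dimensions.

    Axis sign convention: the first nonzero loading of each axis is positive.
    Raises :class:`DimensionError` (carrying the usable rank) when the k-th
    eigenvalue is not positive.
    """
    n = len(dm.labels)
    if not 1 <= k < n:
        raise DimensionError(f"k={k} must be in [1, {n - 1})", usable_rank=n - 1)
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    usable = int(np.sum(evals > 1e-9 * max(1.0, abs(evals[0]))))
    if k > usable:
        raise DimensionError(
            f"requested k={k} axes but only {usable} positive eigenvalues",
            usable_rank=usable)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for ax in range(k):
        col = coords[:, ax]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, ax] = -col
    return pd.DataFrame(coords, index=dm.labels,
                        columns=[f"axis{i + 1}" for i in range(k)])


# --- neighbor-joining -------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor-joining with deterministic lexicographic
    tie-breaking and negative branch lengths clamped to 0 (recorded)."""
    if len(dm.labels) < 3:
        raise InputError("neighbor-joining needs at least 3 labels")
    if not np.isfinite(dm.values).all():
        raise InputError("non-finite distances")

    nodes: dict[str, _Node] = {lab: _Node(lab) for lab in dm.labels}
    d: dict[tuple[str, str], float] = {}
    active = list(dm.labels)
    for i, a in enumerate(active):
        for j, b in enumerate(active):
            if i < j:
                d[(a, b)] = float(dm.values[i, j])

    def dist(a: str, b: str) -> float:
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    clamped: list[tuple[str, str]] = []

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            clamped.append((a, b))
            return 0.0
        return x

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = tuple(sorted((nodes[a].min_leaf, nodes[b].min_leaf)))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or key < best[2])):
                    best, best_q = (a, b, key), q
        a, b, _ = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        la, lb = clamp(la, a, b), clamp(lb, b, a)
        counter += 1
        new = f"__nj{counter}"
        nodes[new] = _Node(children=[(nodes[a], la), (nodes[b], lb)])
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root = _Node(children=[(nodes[a], clamp(la, a, "root")),
                           (nodes[b], clamp(lb, b, "root")),
                           (nodes[c], clamp(lc, c, "root"))])
    return PhyloTree(root=root, clamped_branches=clamped)


# --- variable positions -----------------------------------------------------

def classify_side_chain(residue: str) -> str:
    """Five-way side-chain classification: negative (D,E), positive (R,H,K),
    polar-uncharged (S,T,N,Q), hydrophobic (A,V,I,L,M,F,Y,W), special (C,G,P)."""
    try:
        return _CLASS_OF[residue.upper()]
    except KeyError:
        raise InputError(f"non-standard amino acid {residue!r}") from None


def variable_positions(aln: Alignment,
                       locations: str | None = None) -> VariantTable:
    """Every alignment column with ≥ 2 distinct non-gap residues, reported
    1-based.  ``locations`` is an optional per-column E/M/C string (from the
    topology module) recorded alongside."""
    rows = []
    for i in range(aln.length):
        col = aln.column(i)
        states = sorted(set(col) - {GAP})
        if len(states) < 2:
            continue
        row = {"position": i + 1}
        for rec in aln.records:
            row[rec.id] = rec.residues[i]
        row["classes"] = ",".join(sorted({classify_side_chain(s) for s in states}))
        if locations is not None:
            row["location"] = locations[i]
        rows.append(row)
    return VariantTable(rows=pd.DataFrame(rows))


def selection_table(codon_aln: CodonAlignment, reference_id: str) -> pd.DataFrame:
    """dN, dS and dN/dS of every record against the chosen reference."""
    ref = next((r for r in codon_aln.records if r.id == reference_id), None)
    if ref is None:
        raise InputError(f"reference {reference_id!r} not in alignment")
    rows = []
    for rec in codon_aln.records:
        if rec.id == reference_id:
            continue
        st = nei_gojobori(rec.residues, ref.residues, pair=(rec.id, reference_id))
        rows.append({"id": rec.id, "reference": reference_id,
                     "dN": st.dN, "dS": st.dS,
                     "dN_dS": st.ratio if st.ratio is not None else float("nan")})
    return pd.DataFrame(rows)
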
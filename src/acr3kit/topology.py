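"""Transmembrane topology and secondary structure.

The topology stage replaces HMM/NN predictors with a documented hydropathy
heuristic: Kyte–Doolittle windowed means, threshold-run detection of
membrane-spanning segments, and loop sidedness by the positive-inside rule
(cytoplasmic loops of membrane proteins are enriched in Arg/Lys).
Secondary structure is assigned from coordinates with a Kabsch–Sander
style electrostatic hydrogen-bond energy on geometrically reconstructed
amide hydrogens, which also supports detection of the discontinuous
"α-helix – extended peptide – α-helix" motifs characteristic of
ion-coupled transporters such as Acr3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, StructureError
from .io_core import StructureModel

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class HydropathyProfile:
    sequence: str
    window: int
    values: np.ndarray

    def __post_init__(self):
        if len(self.values) != len(self.sequence):
            raise InputError("profile length must equal sequence length")


@dataclass
class TMTopology:
    """Ordered membrane-spanning segments plus optional per-residue E/M/C
    labels and N-terminal sidedness."""

    n_residues: int
    segments: list[tuple[int, int]] = field(default_factory=list)  # 1-based incl.
    locations: str | None = None  # per-residue E/M/C
    n_terminus_side: str | None = None  # "C" or "E"

    def __post_init__(self):
        prev_end = 0
        for start, end in self.segments:
            if start > end or start <= prev_end:
                raise InputError("segments must be sorted and non-overlapping")
            prev_end = end
        if self.locations is not None and len(self.locations) != self.n_residues:
            raise InputError("locations length must equal n_residues")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_of(self, position: int) -> int | None:
        """1-based segment id containing a residue position, or None."""
        for sid, (start, end) in enumerate(self.segments, start=1):
            if start <= position <= end:
                return sid
        return None


# ---------------------------------------------------------------------------

def hydropathy_profile(seq: str, window: int = 19) -> HydropathyProfile:
    """Sliding-window mean Kyte–Doolittle hydropathy.  Terminal positions use
    the window truncated to the sequence bounds."""
    if window < 1 or window % 2 == 0:
        raise InputError("window must be a positive odd integer")
    try:
        raw = np.array([KYTE_DOOLITTLE[aa] for aa in seq.upper()])
    except KeyError as exc:
        raise InputError(f"non-standard residue {exc.args[0]!r}") from None
    half = window // 2
    n = len(raw)
    values = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        values[i] = raw[lo:hi].mean()
    return HydropathyProfile(sequence=seq, window=window, values=values)


def predict_tm_segments(profile: HydropathyProfile, threshold: float = 1.6,
                        min_len: int = 17, merge_gap: int = 3,
                        max_len: int = 35) -> TMTopology:
    """Membrane-spanning segments as maximal runs of windowed hydropathy
    above ``threshold``; nearby runs (gap ≤ ``merge_gap``) merged, short runs
    (< ``min_len``) discarded, over-long runs (> ``max_len``) split at their
    internal hydropathy minimum."""
    above = profile.values > threshold
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = [r for r in merged if r[1] - r[0] + 1 >= min_len]

    final: list[tuple[int, int]] = []
    stack = list(kept)
    while stack:
        lo, hi = stack.pop(0)
        if hi - lo + 1 > max_len:
            interior = profile.values[lo + 1:hi]
            cut = lo + 1 + int(np.argmin(interior))
            stack.insert(0, [cut + 1, hi])
            stack.insert(0, [lo, cut - 1])
        else:
            final.append((lo + 1, hi + 1))  # to 1-based inclusive
    final.sort()
    return TMTopology(n_residues=len(profile.sequence), segments=final)


def assign_compartments(topology: TMTopology, seq: str) -> TMTopology:
    """Label every residue E (extracellular), M (membrane) or C (cytoplasmic).

    Loops strictly alternate sides; the orientation (whether the N-terminal
    loop is cytoplasmic) is chosen by the positive-inside rule: the
    orientation placing more Arg+Lys on C-side loops wins, ties going to
    N-terminus-cytoplasmic.
    """
    if not topology.segments:
        raise InputError("need at least one membrane segment")
    if len(seq) != topology.n_residues:
        raise InputError("sequence length does not match topology")

    def loop_ranges() -> list[tuple[int, int]]:
        loops = []
        prev = 0
        for start, end in topology.segments:
            loops.append((prev + 1, start - 1))  # may be empty
            prev = end
        loops.append((prev + 1, len(seq)))
        return loops

    loops = loop_ranges()

    def rk_on_c_side(n_term_c: bool) -> int:
        total = 0
        side = "C" if n_term_c else "E"
        for lo, hi in loops:
            if side == "C":
                total += sum(1 for aa in seq[lo - 1:hi] if aa in "RK")
            side = "E" if side == "C" else "C"
        return total

    n_term_c = rk_on_c_side(True) >= rk_on_c_side(False)

    labels = ["M"] * len(seq)
    side = "C" if n_term_c else "E"
    for k, (lo, hi) in enumerate(loops):
        for i in range(lo - 1, hi):
            labels[i] = side
        side = "E" if side == "C" else "C"
    return TMTopology(n_residues=topology.n_residues, segments=topology.segments,
                      locations="".join(labels),
                      n_terminus_side="C" if n_term_c else "E")


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

_KS_Q = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander coupling constant
_KS_CUTOFF = -0.5


def _backbone_arrays(model: StructureModel) -> dict[str, np.ndarray]:
    out = {}
    for name in ("N", "CA", "C", "O"):
        rows = []
        for ridx in model.residue_indices:
            a = model.atom(ridx, name)
            if a is None:
                raise StructureError(
                    f"residue {ridx} ({model.residue_name(ridx)}) lacks "
                    f"backbone atom {name}")
            rows.append(a.coords)
        out[name] = np.asarray(rows)
    return out


def reconstruct_amide_hydrogens(model: StructureModel) -> np.ndarray:
    """(n, 3) amide-H positions; row 0 is NaN (no preceding carbonyl).

    H sits 1.01 Å from N along the external bisector of the N–C(prev) and
    N–CA bonds (the trans-amide direction)."""
    bb = _backbone_arrays(model)
    n_res = bb["N"].shape[0]
    h = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        u = bb["N"][i] - bb["C"][i - 1]
        v = bb["N"][i] - bb["CA"][i]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        w = u + v
        h[i] = bb["N"][i] + 1.01 * w / np.linalg.norm(w)
    return h


def backbone_hbonds(model: StructureModel) -> list[tuple[int, int, float]]:
    """Backbone N–H…O=C bonds by Kabsch–Sander energy.

    Returns (donor_residue, acceptor_residue, energy) with 1-based indices;
    a bond exists when E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
    < −0.5 kcal/mol.
    """
    bb = _backbone_arrays(model)
    h = reconstruct_amide_hydrogens(model)
    n_res = bb["N"].shape[0]
    bonds = []
    for i in range(1, n_res):  # donor N-H of residue i (0-based)
        if not np.isfinite(h[i]).all():
            continue
        for j in range(n_res):  # acceptor C=O of residue j
            if j in (i, i - 1):
                continue
            r_on = np.linalg.norm(bb["O"][j] - bb["N"][i])
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(bb["C"][j] - h[i])
            r_oh = np.linalg.norm(bb["O"][j] - h[i])
            r_cn = np.linalg.norm(bb["C"][j] - bb["N"][i])
            e = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _KS_CUTOFF:
                bonds.append((i + 1, j + 1, float(e)))
    return bonds


def assign_secondary_structure(model: StructureModel) -> str:
    """Per-residue H/E/C string from backbone hydrogen-bond patterns.

    H: residue covered by an i→i+4 backbone bond (donor N-H of residue i+4
    to carbonyl of residue i).  E: residue in a non-local bond (sequence
    separation ≥ 5) not already helix.  C: otherwise.  Deterministic.
    """
    n = model.residue_count
    labels = ["C"] * n
    bonds = backbone_hbonds(model)
    in_nonlocal = set()
    for donor, acceptor, _ in bonds:
        if donor - acceptor == 4:
            for k in range(acceptor, donor + 1):
                labels[k - 1] = "H"
        elif abs(donor - acceptor) >= 5:
            in_nonlocal.add(donor)
            in_nonlocal.add(acceptor)
    for r in in_nonlocal:
        if labels[r - 1] != "H":
            labels[r - 1] = "E"
    return "".join(labels)


def detect_discontinuous_helices(ss: str, topology: TMTopology,
                                 min_arm: int = 4, max_break: int = 6
                                 ) -> list[dict]:
    """Find "helix – extended peptide – helix" motifs inside membrane
    segments: an H-run of ≥ min_arm, a 1..max_break non-H break, then another
    H-run of ≥ min_arm.  Ranges are 1-based inclusive in residue coordinates.
    """
    if len(ss) != topology.n_residues:
        raise InputError("secondary-structure string does not match topology")
    motifs = []
    pattern = re.compile(
        rf"(H{{{min_arm},}})([^H]{{1,{max_break}}})(H{{{min_arm},}})")
    for sid, (start, end) in enumerate(topology.segments, start=1):
        sub = ss[start - 1:end]
        pos = 0
        while True:
            m = pattern.search(sub, pos)
            if m is None:
                break
            offset = start  # 1-based offset of sub[0]
            arm1 = (offset + m.start(1), offset + m.end(1) - 1)
            brk = (offset + m.start(2), offset + m.end(2) - 1)
            arm2 = (offset + m.start(3), offset + m.end(3) - 1)
            motifs.append({"segment": sid, "arm1": arm1, "break": brk,
                           "arm2": arm2})
            pos = m.start(3)  # second arm may start the next motif
    return motifs
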
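"""Readers and writers for the plain-text formats the pipeline touches.

Sequences travel as FASTA, structures as single-chain PDB coordinate files
(ATOM records only), tables as TSV and run manifests as JSON.  Readers
preserve input order and never sort silently.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, StructureError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class SequenceRecord:
    """A single FASTA record (protein or nucleotide)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_index: int  # 1-based index in the parsed model (consecutive)
    x: float
    y: float
    z: float
    element: str = ""
    original_index: int = 0  # residue number as written in the source file

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class StructureModel:
    """A single-chain protein model: atoms grouped contiguously by residue."""

    model_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        seen: list[int] = []
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise StructureError(f"non-finite coordinates for atom {a.serial}")
            if not seen or seen[-1] != a.residue_index:
                if a.residue_index in seen:
                    raise StructureError(
                        f"atoms of residue {a.residue_index} are not contiguous"
                    )
                seen.append(a.residue_index)
        for idx in seen:
            names = [a.atom_name for a in self.atoms if a.residue_index == idx]
            if "CA" not in names:
                raise StructureError(f"residue {idx} has no CA atom")

    @property
    def residue_count(self) -> int:
        return len({a.residue_index for a in self.atoms})

    @property
    def residue_indices(self) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if not out or out[-1] != a.residue_index:
                out.append(a.residue_index)
        return out

    @property
    def sequence(self) -> str:
        letters = []
        for idx in self.residue_indices:
            name = self.residue_name(idx)
            letters.append(THREE_TO_ONE.get(name, "X"))
        return "".join(letters)

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise StructureError(f"no residue {residue_index} in model {self.model_id}")

    def residue_atoms(self, residue_index: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_index == residue_index]

    def atom(self, residue_index: int, atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return a
        return None

    def ca_coords(self) -> np.ndarray:
        """(n_residues, 3) array of CA coordinates in residue order."""
        rows = []
        for idx in self.residue_indices:
            ca = self.atom(idx, "CA")
            if ca is None:
                raise StructureError(f"residue {idx} has no CA atom")
            rows.append([ca.x, ca.y, ca.z])
        return np.asarray(rows, dtype=float)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of all atom coordinates in file order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file, preserving record order.

    Raises :class:`FormatError` on empty files, missing headers and records
    with empty sequences.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {header!r}")
        sid, _, desc = header.partition(" ")
        records.append(SequenceRecord(id=sid, residues=seq, description=desc.strip()))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FormatError(f"{path}: FASTA header with no identifier")
            chunks = []
        else:
            if header is None:
                raise FormatError(f"{path}: sequence data before first header")
            chunks.append(line.replace(" ", ""))
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_structure(path: str | os.PathLike, chain: str | None = None,
                   model_id: str | None = None) -> StructureModel:
    """Read one chain of a PDB-format coordinate file.

    Only ``ATOM`` records of the selected chain (default: the first chain
    encountered) are kept.  HETATM records, waters and alternate locations
    other than the first are discarded.  Residues are renumbered 1..N in
    order of appearance; the source-file residue number is retained in
    ``AtomRecord.original_index``.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    selected_chain = chain
    seen_residues: dict[tuple[str, int, str], int] = {}
    seen_atoms: set[tuple[int, str]] = set()
    next_index = 0

    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            chain_id = line[21]
            if selected_chain is None:
                selected_chain = chain_id
            if chain_id != selected_chain:
                continue
            altloc = line[16]
            resname = line[17:20].strip()
            resseq = int(line[22:26])
            icode = line[26]
            key = (resname, resseq, icode)
            if key not in seen_residues:
                next_index += 1
                seen_residues[key] = next_index
            ridx = seen_residues[key]
            name = line[12:16].strip()
            if altloc not in (" ", "A", "1") or (ridx, name) in seen_atoms:
                continue  # keep first alternate location only
            seen_atoms.add((ridx, name))
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name.lstrip("0123456789")[:1]
            atoms.append(AtomRecord(
                serial=int(line[6:11]),
                atom_name=name,
                residue_name=resname,
                chain_id=chain_id,
                residue_index=ridx,
                x=float(line[30:38]), y=float(line[38:46]), z=float(line[46:54]),
                element=element,
                original_index=resseq,
            ))
    if not atoms:
        raise FormatError(f"{path}: no ATOM records for chain {chain!r}")
    return StructureModel(model_id=model_id or path.stem, atoms=atoms)


def write_structure(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a model as minimal PDB ATOM records (fixed-column, 3-decimal Å)."""
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            name = a.atom_name
            name_field = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                f"ATOM  {i:5d} {name_field}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_index:4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Output bundle / manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_tsv(df, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(labels: Sequence[str], values: np.ndarray,
                     path: str | os.PathLike) -> None:
    """Square labelled matrix as TSV with row and column labels."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, np.asarray(values)):
            fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_outputs(bundle: Mapping[str, object], out_dir: str | os.PathLike) -> dict:
    """Emit every section of a result bundle and a JSON manifest.

    Dispatch is on object type: DataFrames become TSV, sequence-record lists
    become FASTA, objects exposing ``to_newick``/``to_tsv_frame``/``to_dict``
    use those hooks, plain mappings become JSON, strings become ``.txt``.
    Returns the manifest (also written to ``manifest.json``).
    """
    import pandas as pd

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir!r} is not writable: {exc}") from exc

    files: list[dict] = []
    for name, obj in bundle.items():
        if obj is None:
            continue
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            write_tsv(obj, path)
        elif isinstance(obj, StructureModel):
            path = out / f"{name}.pdb"
            write_structure(obj, path)
        elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], SequenceRecord):
            path = out / f"{name}.fasta"
            write_fasta(obj, path)
        elif hasattr(obj, "to_newick"):
            path = out / f"{name}.nwk"
            path.write_text(obj.to_newick() + "\n")
        elif hasattr(obj, "to_tsv_frame"):
            path = out / f"{name}.tsv"
            write_tsv(obj.to_tsv_frame(), path)
        elif hasattr(obj, "labels") and hasattr(obj, "values"):
            path = out / f"{name}.tsv"
            write_matrix_tsv(obj.labels, obj.values, path)
        elif isinstance(obj, str):
            path = out / f"{name}.txt"
            path.write_text(obj + ("\n" if not obj.endswith("\n") else ""))
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=_json_default,
                                       sort_keys=True) + "\n")
        files.append({"name": name, "file": path.name, "sha256": _sha256(path)})

    manifest = {"files": files, "n_files": len(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    return str(obj)
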
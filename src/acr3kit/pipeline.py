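"""Config-driven orchestration of the full comparative analysis.

``run_full_analysis`` runs, in order: sequence loading → alignment →
selection statistics (dN/dS vs reference) → identity/MDS/NJ clustering →
variable positions → per-sequence topology → per-structure secondary
structure and contact maps → pairwise contact differencing → interaction
networks and hydrogen bonds at key residues → per-residue binding
energies at variable residues.  Each stage records success or failure;
independent stages continue past a failed one.  Everything is
deterministic given config + seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energetics, io_core, seq_evolution, struct_compare, topology
from .errors import Acr3KitError, ConfigError

log = logging.getLogger("acr3kit")


@dataclass
class AnalysisConfig:
    structures: dict[str, str] = field(default_factory=dict)  # id -> PDB path
    cds_fasta: str | None = None
    protein_fasta: str | None = None
    reference_id: str | None = None
    contact_cutoff: float = 8.0
    network_radius: float = 5.0
    key_residues: list[int] = field(default_factory=lambda: [107, 294])
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 17
    tm_merge_gap: int = 3
    hbond_distance: float = 3.0
    hbond_angle: float = 20.0
    cluster_k: int | None = None
    energy_radius: float = 5.0
    max_energy_residues: int = 30
    seed: int = 0
    out_dir: str = "acr3kit_out"

    def validate(self) -> None:
        if self.contact_cutoff <= 0 or self.network_radius <= 0:
            raise ConfigError("cutoffs must be positive")
        for sid, path in self.structures.items():
            if not Path(path).exists():
                raise ConfigError(f"structure file for {sid!r} missing: {path}")
        for label, path in (("cds_fasta", self.cds_fasta),
                            ("protein_fasta", self.protein_fasta)):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} missing: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ReportBundle:
    sections: dict[str, object] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str) -> dict:
        bundle = dict(self.sections)
        bundle["run_metadata"] = {"config": self.metadata,
                                  "skipped": self.skipped}
        return io_core.write_outputs(bundle, out_dir)


def _stage(bundle: ReportBundle, name: str, fn, *deps: str):
    for dep in deps:
        if dep in bundle.skipped:
            bundle.skipped[name] = f"dependency {dep!r} failed"
            log.warning("stage %s skipped (%s)", name, bundle.skipped[name])
            return None
    t0 = time.perf_counter()
    try:
        result = fn()
    except Acr3KitError as exc:
        bundle.skipped[name] = f"{type(exc).__name__}: {exc}"
        log.warning("stage %s failed: %s", name, exc)
        return None
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
    if result is not None:
        bundle.sections[name] = result
    return result


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    config.validate()
    bundle = ReportBundle(metadata=config.echo())

    proteins = cds = None
    if config.protein_fasta:
        proteins = _stage(bundle, "proteins",
                          lambda: io_core.read_fasta(config.protein_fasta))
    if config.cds_fasta:
        cds = _stage(bundle, "cds", lambda: io_core.read_fasta(config.cds_fasta))

    models: dict[str, io_core.StructureModel] = {}
    if config.structures:
        def load_models():
            for sid, path in config.structures.items():
                models[sid] = io_core.read_structure(path, model_id=sid)
            return None
        _stage(bundle, "load_structures", load_models)
    if proteins is None and models:
        proteins = [io_core.SequenceRecord(id=sid, residues=m.sequence)
                    for sid, m in models.items()]
        bundle.sections["proteins"] = proteins

    aln = None
    if proteins and len(proteins) >= 2:
        if len({len(p.residues) for p in proteins}) == 1:
            aln = seq_evolution.Alignment(records=list(proteins))
            bundle.sections["protein_alignment"] = aln.records
        else:
            bundle.skipped["protein_alignment"] = \
                "unaligned inputs of unequal length; provide an alignment"

    codon_aln = None
    if aln is not None and cds:
        codon_aln = _stage(
            bundle, "codon_alignment",
            lambda: seq_evolution.back_translate_alignment(
                aln, {r.id: r for r in cds}))
        if codon_aln is not None:
            bundle.sections["codon_alignment"] = codon_aln.records

    if codon_aln is not None and config.reference_id:
        _stage(bundle, "selection_stats",
               lambda: seq_evolution.selection_table(codon_aln,
                                                     config.reference_id))

    dm = None
    if proteins and len(proteins) >= 2:
        dm = _stage(bundle, "identity_distance",
                    lambda: seq_evolution.identity_matrix(
                        [io_core.SequenceRecord(r.id, r.residues.replace("-", ""))
                         for r in proteins]))
    if dm is not None:
        _stage(bundle, "mds_coordinates",
               lambda: seq_evolution.classical_mds(
                   dm, k=min(2, len(dm.labels) - 1)).rename_axis("id").reset_index())
        if len(dm.labels) >= 3:
            _stage(bundle, "nj_tree", lambda: seq_evolution.nj_tree(dm))

    variants = None
    if aln is not None:
        variants = _stage(bundle, "variant_table",
                          lambda: seq_evolution.variable_positions(aln))

    topo = None
    if proteins:
        def topo_stage():
            seq = proteins[0].residues.replace("-", "")
            prof = topology.hydropathy_profile(seq, window=config.tm_window)
            segs = topology.predict_tm_segments(
                prof, threshold=config.tm_threshold,
                min_len=config.tm_min_len, merge_gap=config.tm_merge_gap)
            if segs.segments:
                return topology.assign_compartments(segs, seq)
            return segs
        topo = _stage(bundle, "tm_topology", topo_stage)
        if topo is not None:
            bundle.sections["tm_topology"] = pd.DataFrame(
                [{"segment": i + 1, "start": s, "end": e}
                 for i, (s, e) in enumerate(topo.segments)])
            if topo.locations:
                bundle.sections["residue_locations"] = topo.locations

    contact_maps: dict[str, struct_compare.ContactMap] = {}
    if models:
        def maps_stage():
            rows = []
            for sid, m in models.items():
                cm = struct_compare.build_contact_map(m, config.contact_cutoff)
                contact_maps[sid] = cm
                ss = topology.assign_secondary_structure(m)
                rows.append({"model": sid, "n_residues": m.residue_count,
                             "n_contacts": cm.total,
                             "helix_fraction": ss.count("H") / len(ss)})
            return pd.DataFrame(rows)
        _stage(bundle, "contact_summary", maps_stage)

        if len(models) >= 2:
            def diffs_stage():
                rows = []
                ids = list(models)
                for i, a in enumerate(ids):
                    for b in ids[i + 1:]:
                        d = struct_compare.diff_contact_maps(
                            contact_maps[a], contact_maps[b],
                            models[a].sequence, models[b].sequence)
                        rows.append({"model_a": a, "model_b": b, **d.counts})
                return pd.DataFrame(rows)
            _stage(bundle, "contact_diffs", diffs_stage, "contact_summary")

            _stage(bundle, "structure_clusters",
                   lambda: pd.DataFrame(
                       [{"model": mid, "cluster": lab}
                        for mid, lab in struct_compare.cluster_structures(
                            list(models.values()), k=config.cluster_k
                        ).labels.items()]))

        def networks_stage():
            rows = []
            for sid, m in models.items():
                for kr in config.key_residues:
                    if kr > m.residue_count:
                        continue
                    net = struct_compare.interaction_network(
                        m, kr, radius=config.network_radius)
                    rows.append({"model": sid, "focal": kr,
                                 "partners": ",".join(
                                     str(p) for p in sorted(net.partner_set))})
            return pd.DataFrame(rows)
        _stage(bundle, "interaction_networks", networks_stage)

        def hbond_stage():
            rows = []
            focal = list(config.key_residues)
            if variants is not None:
                focal = sorted(set(focal) | set(variants.positions))
            for sid, m in models.items():
                for fr in focal:
                    if fr > m.residue_count:
                        continue
                    bonds = struct_compare.hbonds_near_residue(
                        m, fr, radius=config.network_radius,
                        d_cutoff=config.hbond_distance,
                        angle_cutoff=config.hbond_angle)
                    rows.append({"model": sid, "focal": fr,
                                 "pairs": " ; ".join(
                                     struct_compare.hbond_table_rows(m, bonds))})
            return pd.DataFrame(rows)
        _stage(bundle, "hbond_tables", hbond_stage)

        def energy_stage():
            focal = variants.positions if variants is not None else []
            focal = [p for p in focal][:config.max_energy_residues]
            if not focal:
                focal = [p for p in config.key_residues]
            frames = []
            for sid, m in models.items():
                usable = [p for p in focal if p <= m.residue_count]
                if not usable:
                    continue
                pm = energetics.assign_parameters(m)
                df = energetics.binding_energy_table(
                    pm, usable, radius=config.energy_radius)
                df.insert(0, "model", sid)
                frames.append(df)
            return pd.concat(frames, ignore_index=True) if frames else None
        _stage(bundle, "binding_energies", energy_stage)

    return bundle
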
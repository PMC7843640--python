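"""End-to-end orchestration: fixture generation and the comparative analysis.

``generate_fixtures`` fabricates a three-homolog synthetic study set
(structures, trajectories, sequences and a plain-text ground-truth sidecar).
``run_pipeline`` executes the full comparison on any conforming inputs:
load -> structure/sequence consistency -> multiple alignment + common
numbering -> per-protein RMSD and RMSF -> RMSF-difference regions ->
interaction candidates, distance series and the cross-homolog table ->
tidy CSV outputs plus a JSON run report.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from typing import Any

import numpy as np
import pandas as pd

from . import interactions as inter
from .config import GeneratorConfig, RunConfig
from .core import SequenceRecord, Structure, Trajectory
from .io import read_fasta, read_pdb, write_fasta, write_pdb
from .mapping import (
    AlignParams,
    align_many,
    build_map,
    check_structure_sequence,
    percent_identity,
)
from .regions import delta_profile, detect_regions, map_regions_to_proteins
from .superpose import rmsf, trajectory_rmsd
from .synthetic import (
    FluctuationSpec,
    InteractionPlan,
    make_homolog_set,
    make_reference_structure,
    make_trajectory,
    n_frames_from_duration,
    place_planted_pairs,
)

__all__ = ["RunReport", "run_pipeline", "generate_fixtures", "StageError"]

logger = logging.getLogger(__name__)

# planted interaction motifs on base-sequence numbering:
# (name, kind, residue pair, forced residues, per-role occupancy)
_MOTIFS = (
    {
        "name": "K12-D82",
        "kind": "salt_bridge",
        "pair": (12, 82),
        "force": {12: "K", 82: "D"},
        "atoms": ("NZ", "OD1"),
        "occupancy": {"hyperthermophile": 0.9, "thermophile": 0.6, "mesophile": None},
        "mesophile_replacement": {12: "M"},  # Met cannot form the bridge
    },
    {
        "name": "R25-E26",
        "kind": "salt_bridge",
        "pair": (25, 26),
        "force": {25: "R", 26: "E"},
        "atoms": ("NE", "OE1"),
        "occupancy": {"hyperthermophile": 0.9, "thermophile": 0.2, "mesophile": 0.2},
    },
    {
        "name": "T36-T39",
        "kind": "hydrogen_bond",
        "pair": (36, 39),
        "force": {36: "T", 39: "T"},
        "atoms": ("OG1", "OG1"),
        "occupancy": {"hyperthermophile": 0.8, "thermophile": 0.1, "mesophile": 0.05},
    },
    {
        "name": "R81-E90",
        "kind": "salt_bridge",
        "pair": (81, 90),
        "force": {81: "R", 90: "E"},
        "atoms": ("NE", "OE1"),
        "occupancy": {"hyperthermophile": 0.85, "thermophile": 0.0, "mesophile": 0.6},
    },
)

_BOUND = {"salt_bridge": 2.9, "hydrogen_bond": 2.8}
_UNBOUND = {"salt_bridge": 8.0, "hydrogen_bond": 7.5}


class StageError(RuntimeError):
    """A pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunReport:
    """Everything a run produced, with provenance."""

    config: dict[str, Any]
    identities_pct: dict[str, float]
    rmsd_summary: dict[str, float]
    rmsf_summary: dict[str, float]
    regions: list[dict[str, Any]]
    region_spans: dict[str, list[dict[str, Any]]]
    mean_delta_A: float
    comparison: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "identities_pct": self.identities_pct,
            "rmsd_mean_A": self.rmsd_summary,
            "rmsf_mean_A": self.rmsf_summary,
            "mean_delta_A": self.mean_delta_A,
            "regions": self.regions,
            "region_spans": self.region_spans,
            "interaction_comparison": self.comparison.to_dict(orient="records"),
            "warnings": self.warnings,
            "provenance": self.provenance,
        }


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, exc) from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full comparative analysis described by ``config``.

    Outputs are written to ``config.output_dir``: tidy CSVs (RMSD, RMSF,
    alignment map, delta profile, regions, interaction distances and the
    cross-homolog comparison), the alignment as aligned FASTA, a BED-like
    interval file over the common numbering, and ``report.json``.
    """
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    warnings: list[str] = []

    @_stage("load")
    def load():
        structures: dict[str, Structure] = {}
        trajectories: dict[str, Trajectory] = {}
        records: dict[str, SequenceRecord] = {}
        for p in config.proteins:
            struct = read_pdb(p.structure_path)
            if isinstance(struct, Trajectory):
                raise ValueError(f"{p.structure_path} is multi-model; expected one")
            struct.name = p.id
            traj = read_pdb(
                p.trajectory_path,
                frame_interval=config.frame_interval_ps,
                temperature=config.temperature_K,
            )
            if isinstance(traj, Structure):
                traj = Trajectory(
                    topology=traj,
                    frames=traj.coords[None],
                    frame_interval=config.frame_interval_ps,
                    temperature=config.temperature_K,
                )
            traj.topology.name = p.id
            fasta = {r.id: r for r in read_fasta(p.sequence_path)}
            if p.id not in fasta:
                raise ValueError(f"no FASTA record {p.id!r} in {p.sequence_path}")
            structures[p.id] = struct
            trajectories[p.id] = traj
            records[p.id] = fasta[p.id]
        return structures, trajectories, records

    structures, trajectories, records = load()

    @_stage("consistency")
    def consistency():
        for pid, struct in structures.items():
            check_structure_sequence(struct, records[pid])

    consistency()

    params = config.analysis
    align_params = AlignParams(
        matrix=params.matrix, gap_open=params.gap_open, gap_extend=params.gap_extend
    )

    @_stage("alignment")
    def alignment_stage():
        alignment = align_many(list(records.values()), align_params)
        amap = build_map(alignment)
        identities = {}
        ids = alignment.ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                identities[f"{a}|{b}"] = percent_identity(alignment, a, b)
        return alignment, amap, identities

    alignment, amap, identities = alignment_stage()

    @_stage("fluctuations")
    def fluctuations():
        rmsd_series = {}
        rmsf_profiles = {}
        for pid, traj in trajectories.items():
            rmsd_series[pid] = trajectory_rmsd(
                traj,
                structures[pid],
                atom_selection=params.atom_selection,
                burn_in_frames=params.burn_in_frames,
            )
            rmsf_profiles[pid] = rmsf(
                traj,
                atom_selection=params.atom_selection,
                burn_in_frames=params.burn_in_frames,
            )
        return rmsd_series, rmsf_profiles

    rmsd_series, rmsf_profiles = fluctuations()

    @_stage("regions")
    def regions_stage():
        dprof = delta_profile(
            rmsf_profiles, amap, config.mesophile_id, config.thermophile_ids
        )
        regs = detect_regions(
            dprof,
            min_length=params.min_region_length,
            gap_tolerance=params.region_gap_tolerance,
        )
        spans = map_regions_to_proteins(regs, amap)
        return dprof, regs, spans

    dprof, regs, spans = regions_stage()

    @_stage("interactions")
    def interactions_stage():
        series_by_protein: dict[str, list[inter.InteractionSeries]] = {}
        distance_frames = []
        for pid, traj in trajectories.items():
            series_list = []
            for kind, cutoff in (
                ("salt_bridge", params.salt_bridge_cutoff_A),
                ("hydrogen_bond", params.hbond_cutoff_A),
            ):
                for pair in inter.candidate_pairs(
                    structures[pid], kind, search_cutoff=params.search_cutoff_A
                ):
                    series = inter.distance_series(
                        traj,
                        pair,
                        cutoff=cutoff,
                        presence_threshold=params.presence_threshold,
                    )
                    series_list.append(series)
                    distance_frames.append(series.to_frame(pid, traj.frame_times))
            series_by_protein[pid] = series_list
        table = inter.compare_across_homologs(
            series_by_protein,
            amap,
            sequences={pid: r.sequence for pid, r in records.items()},
            presence_threshold=params.presence_threshold,
        )
        distances = (
            pd.concat(distance_frames, ignore_index=True)
            if distance_frames
            else pd.DataFrame(
                columns=["protein", "pair", "kind", "frame_time_ps", "distance_A"]
            )
        )
        return table, distances

    comparison, distances = interactions_stage()

    @_stage("report")
    def report_stage() -> RunReport:
        pd.concat(
            [s.to_frame(pid) for pid, s in rmsd_series.items()], ignore_index=True
        ).to_csv(os.path.join(out, "rmsd.csv"), index=False)
        pd.concat(
            [p.to_frame(pid) for pid, p in rmsf_profiles.items()], ignore_index=True
        ).to_csv(os.path.join(out, "rmsf.csv"), index=False)
        with open(os.path.join(out, "alignment.fasta"), "w") as fh:
            for sid, row in zip(alignment.ids, alignment.rows):
                fh.write(f">{sid}\n")
                for k in range(0, len(row), 60):
                    fh.write(row[k : k + 60] + "\n")
        map_rows = []
        for sid in amap.ids:
            for residue, col in sorted(amap.to_column[sid].items()):
                map_rows.append(
                    {
                        "protein": sid,
                        "residue_number": residue,
                        "common_column": col,
                        "is_gap_column": False,
                    }
                )
            for col in sorted(amap.gap_columns[sid]):
                map_rows.append(
                    {
                        "protein": sid,
                        "residue_number": pd.NA,
                        "common_column": col,
                        "is_gap_column": True,
                    }
                )
        pd.DataFrame(map_rows).to_csv(
            os.path.join(out, "alignment_map.csv"), index=False
        )
        dprof.to_frame().to_csv(os.path.join(out, "delta_profile.csv"), index=False)
        region_rows = []
        for r in regs:
            row = {
                "label": r.label,
                "start_column": r.start_column,
                "end_column": r.end_column,
                "length": r.length,
                "mean_delta_in_region_A": round(r.mean_delta_in_region, 4),
            }
            for pid in amap.ids:
                span = next(s for s in spans[pid] if s["label"] == r.label)
                row[f"{pid}_span"] = (
                    "-"
                    if span["all_gap"]
                    else f"{span['start_residue']}-{span['end_residue']}"
                )
            region_rows.append(row)
        pd.DataFrame(
            region_rows,
            columns=["label", "start_column", "end_column", "length", "mean_delta_in_region_A"]
            + [f"{pid}_span" for pid in amap.ids],
        ).to_csv(os.path.join(out, "regions.csv"), index=False)
        with open(os.path.join(out, "regions.intervals.txt"), "w") as fh:
            fh.write("# common numbering, 1-based inclusive\n")
            for r in regs:
                fh.write(f"common\t{r.start_column}\t{r.end_column}\t{r.label}\n")
        distances.to_csv(os.path.join(out, "interaction_distances.csv"), index=False)
        comparison.to_csv(os.path.join(out, "interaction_comparison.csv"), index=False)

        try:
            pkg_version = _pkg_version("thermofluct")
        except Exception:  # pragma: no cover - not installed
            pkg_version = "unknown"
        report = RunReport(
            config=config.echo(),
            identities_pct=identities,
            rmsd_summary={
                pid: round(float(np.mean(s.values)), 4)
                for pid, s in rmsd_series.items()
            },
            rmsf_summary={
                pid: round(float(np.mean(p.values)), 4)
                for pid, p in rmsf_profiles.items()
            },
            regions=[
                {
                    "label": r.label,
                    "start_column": r.start_column,
                    "end_column": r.end_column,
                    "length": r.length,
                    "mean_delta_in_region_A": round(r.mean_delta_in_region, 4),
                }
                for r in regs
            ],
            region_spans=spans,
            mean_delta_A=round(dprof.mean_delta, 4),
            comparison=comparison,
            warnings=warnings,
            provenance={
                "package_version": pkg_version,
                "identity_denominator": "columns without gaps in either sequence",
                "delta_convention": "mesophile RMSF minus mean over thermophiles; "
                "gap columns excluded from profile and average",
                "atom_selection": params.atom_selection,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
        )
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, default=str)
        return report

    return report_stage()


def _build_study_sequences(config: GeneratorConfig, rng: np.random.Generator):
    """Base (hyperthermophile) sequence plus thermophile/mesophile variants."""
    from .synthetic import GENERATOR_ALPHABET

    base = [str(rng.choice(list(GENERATOR_ALPHABET))) for _ in range(config.base_length)]
    protected: set[int] = set()
    for motif in _MOTIFS:
        for pos, letter in motif["force"].items():
            base[pos - 1] = letter
            protected.add(pos)
    base_seq = "".join(base)

    ids = config.protein_ids
    thermo_records, _ = make_homolog_set(
        base_seq,
        1,
        config.thermophile_substitution_rate,
        config.indel_rate,
        seed=int(rng.integers(2**31)),
        ids=[ids["thermophile"]],
        protected_positions=protected,
    )
    meso_records, _ = make_homolog_set(
        base_seq,
        1,
        config.mesophile_substitution_rate,
        config.indel_rate,
        seed=int(rng.integers(2**31)),
        ids=[ids["mesophile"]],
        protected_positions=protected,
    )
    meso_seq = list(meso_records[0].sequence)
    for motif in _MOTIFS:
        for pos, letter in motif.get("mesophile_replacement", {}).items():
            meso_seq[pos - 1] = letter
    extension = [
        str(rng.choice(list(GENERATOR_ALPHABET)))
        for _ in range(config.mesophile_extension)
    ]
    sequences = {
        ids["hyperthermophile"]: base_seq,
        ids["thermophile"]: thermo_records[0].sequence,
        ids["mesophile"]: "".join(meso_seq + extension),
    }
    return sequences


def _plans_for_role(role: str, config: GeneratorConfig) -> list[InteractionPlan]:
    plans = []
    for motif in _MOTIFS:
        occupancy = motif["occupancy"][role]
        if occupancy is None:  # motif chemically absent in this homolog
            continue
        plans.append(
            InteractionPlan(
                residue_pair=motif["pair"],
                atom_pair=motif["atoms"],
                bound_distance=_BOUND[motif["kind"]],
                unbound_distance=_UNBOUND[motif["kind"]],
                occupancy=occupancy,
                jitter_sigma=config.jitter_sigma_A,
            )
        )
    return plans


def generate_fixtures(config: GeneratorConfig, out_dir: str | os.PathLike) -> dict:
    """Write the synthetic study set; deterministic per seed.

    Produces ``{id}.pdb`` (reference), ``{id}_traj.pdb`` (multi-model
    trajectory), ``sequences.fasta``, ``ground_truth.json`` (planted sigmas,
    regions, occupancies) and ``analysis_config.yaml`` ready for ``analyze``.
    """
    import yaml

    config.validate()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    n_frames = config.n_frames or n_frames_from_duration(
        config.duration_ns, config.frame_interval_ps
    )
    rng = np.random.default_rng(config.seed)
    sequences = _build_study_sequences(config, rng)
    ids = config.protein_ids
    roles = {pid: role for role, pid in ids.items()}
    ground_truth: dict[str, Any] = {
        "seed": config.seed,
        "n_frames": n_frames,
        "frame_interval_ps": config.frame_interval_ps,
        "regions": [list(r) for r in config.regions],
        "region_sigma_A": config.region_sigma_A,
        "proteins": {},
    }
    entries = []
    for pid, seq in sequences.items():
        role = roles[pid]
        struct_seed = int(rng.integers(2**31))
        traj_seed = int(rng.integers(2**31))
        reference = make_reference_structure(
            len(seq), seed=struct_seed, sequence=seq, name=pid
        )
        plans = _plans_for_role(role, config)
        reference = place_planted_pairs(reference, plans, seed=struct_seed)
        baseline = config.baseline_sigma_A[role]
        region_plan = []
        if role == "mesophile":
            region_plan = [
                (start, end, config.region_sigma_A) for start, end in config.regions
            ]
            if config.mesophile_extension:
                region_plan.append(
                    (
                        config.base_length + 1,
                        len(seq),
                        config.region_sigma_A,
                    )
                )
        spec = FluctuationSpec.uniform(
            len(seq),
            baseline,
            region_plan=region_plan,
            rigid_body_noise=config.rigid_body_noise,
            seed=traj_seed,
        )
        traj = make_trajectory(
            reference,
            spec,
            plans,
            n_frames=n_frames,
            frame_interval=config.frame_interval_ps,
            temperature=config.temperature_K,
        )
        write_pdb(reference, os.path.join(out_dir, f"{pid}.pdb"))
        write_pdb(traj, os.path.join(out_dir, f"{pid}_traj.pdb"))
        ground_truth["proteins"][pid] = {
            "role": role,
            "sequence_length": len(seq),
            "baseline_sigma_A": baseline,
            "region_plan": [list(r) for r in region_plan],
            "structure_seed": struct_seed,
            "trajectory_seed": traj_seed,
            "planted_interactions": [
                {
                    "pair": list(p.residue_pair),
                    "atoms": list(p.atom_pair),
                    "occupancy": p.occupancy,
                    "bound_A": p.bound_distance,
                    "unbound_A": p.unbound_distance,
                }
                for p in plans
            ],
        }
        entries.append(
            {
                "id": pid,
                "role": "mesophile" if role == "mesophile" else "thermophile",
                "structure_path": os.path.join(out_dir, f"{pid}.pdb"),
                "trajectory_path": os.path.join(out_dir, f"{pid}_traj.pdb"),
                "sequence_path": os.path.join(out_dir, "sequences.fasta"),
            }
        )
    write_fasta(
        [SequenceRecord(id=pid, sequence=seq) for pid, seq in sequences.items()],
        os.path.join(out_dir, "sequences.fasta"),
    )
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(ground_truth, fh, indent=2)
    analysis_config = {
        "proteins": entries,
        "frame_interval_ps": config.frame_interval_ps,
        "temperature_K": config.temperature_K,
        "output_dir": os.path.join(out_dir, "analysis"),
    }
    with open(os.path.join(out_dir, "analysis_config.yaml"), "w") as fh:
        yaml.safe_dump(analysis_config, fh, sort_keys=False)
    return ground_truth
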
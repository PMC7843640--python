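"""Run configuration: YAML schema, validation and defaults.

Two config kinds exist: an *analysis* config (which proteins to compare,
where their files live, and the analysis parameters) and a *generator*
config (the synthetic study set to fabricate).  Validation happens before
any computation; violations raise :class:`ConfigError`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "AnalysisParams",
    "ProteinEntry",
    "RunConfig",
    "GeneratorConfig",
    "load_run_config",
    "load_generator_config",
]


class ConfigError(ValueError):
    """A configuration schema violation (CLI exit code 2)."""


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with their defaults.

    Distances in Angstrom.  ``atom_selection`` names the atom used for RMSD
    and RMSF (one per residue).  Region calling: columns above the mean RMSF
    difference, bridged across up to ``region_gap_tolerance`` columns, kept
    from ``min_region_length``.  Alignment: BLOSUM62 with affine gaps.
    """

    atom_selection: str = "CA"
    burn_in_frames: int = 0
    salt_bridge_cutoff_A: float = 4.0
    hbond_cutoff_A: float = 3.5
    search_cutoff_A: float = 6.0
    presence_threshold: float = 0.1
    min_region_length: int = 3
    region_gap_tolerance: int = 2
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def validate(self) -> None:
        if self.burn_in_frames < 0:
            raise ConfigError("burn_in_frames must be >= 0")
        for name in ("salt_bridge_cutoff_A", "hbond_cutoff_A", "search_cutoff_A"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.presence_threshold <= 1.0:
            raise ConfigError("presence_threshold must lie in [0, 1]")
        if self.min_region_length < 1 or self.region_gap_tolerance < 0:
            raise ConfigError("invalid region-calling parameters")


@dataclass
class ProteinEntry:
    id: str
    role: str  # "mesophile" | "thermophile"
    structure_path: str
    trajectory_path: str
    sequence_path: str

    def validate(self) -> None:
        if self.role not in ("mesophile", "thermophile"):
            raise ConfigError(
                f"protein {self.id!r}: role must be mesophile or thermophile"
            )
        for attr in ("structure_path", "trajectory_path", "sequence_path"):
            path = getattr(self, attr)
            if not os.path.exists(path):
                raise ConfigError(f"protein {self.id!r}: {attr} {path!r} does not exist")


@dataclass
class RunConfig:
    proteins: list[ProteinEntry]
    frame_interval_ps: float = 400.0
    temperature_K: float | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    output_dir: str = "thermofluct_out"

    def validate(self) -> None:
        if len(self.proteins) < 2:
            raise ConfigError("at least 2 proteins are required")
        ids = [p.id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ConfigError("protein ids must be unique")
        roles = [p.role for p in self.proteins]
        if roles.count("mesophile") != 1:
            raise ConfigError("exactly one protein must have role mesophile")
        if roles.count("thermophile") < 1:
            raise ConfigError("at least one protein must have role thermophile")
        if self.frame_interval_ps <= 0:
            raise ConfigError("frame_interval_ps must be positive")
        for p in self.proteins:
            p.validate()
        self.analysis.validate()

    @property
    def mesophile_id(self) -> str:
        return next(p.id for p in self.proteins if p.role == "mesophile")

    @property
    def thermophile_ids(self) -> list[str]:
        return [p.id for p in self.proteins if p.role == "thermophile"]

    def echo(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class GeneratorConfig:
    """Synthetic study set: a hyperthermophile, a thermophile and a mesophile.

    Defaults emulate the target study conditions: 1,000 frames at 400 ps
    (a 400 ns run) and 358 K; thermophile sequences of 125 residues against
    a 137-residue mesophile (a 12-residue flexible C-terminal extension);
    roughly 50% mesophile-thermophile sequence identity; four planted
    high-fluctuation regions in the mesophile; and four planted interaction
    motifs whose occupancies differ across the homologs (including a
    basic-to-methionine replacement that abolishes one salt bridge in the
    mesophile).  Baseline per-axis sigmas rise from the hyperthermophile to
    the mesophile so overall RMSD reproduces the rigidity ordering.
    """

    seed: int = 1
    n_frames: int | None = None
    duration_ns: float = 400.0
    frame_interval_ps: float = 400.0
    temperature_K: float = 358.0
    base_length: int = 125
    mesophile_extension: int = 12
    thermophile_substitution_rate: float = 0.25
    mesophile_substitution_rate: float = 0.5
    indel_rate: float = 0.0
    rigid_body_noise: tuple[float, float] = (5.0, 1.0)
    baseline_sigma_A: dict[str, float] = field(
        default_factory=lambda: {
            "hyperthermophile": 0.25,
            "thermophile": 0.35,
            "mesophile": 0.45,
        }
    )
    region_sigma_A: float = 0.9
    regions: tuple[tuple[int, int], ...] = ((10, 27), (34, 41), (78, 91), (103, 112))
    jitter_sigma_A: float = 0.25
    protein_ids: dict[str, str] = field(
        default_factory=lambda: {
            "hyperthermophile": "hyperMGS",
            "thermophile": "thermoMGS",
            "mesophile": "mesoMGS",
        }
    )

    def validate(self) -> None:
        if self.n_frames is not None and self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.frame_interval_ps <= 0 or self.duration_ns <= 0:
            raise ConfigError("frame bookkeeping values must be positive")
        if self.base_length < 20:
            raise ConfigError("base_length must be at least 20 residues")
        for start, end in self.regions:
            if not (1 <= start <= end <= self.base_length):
                raise ConfigError(f"region ({start}, {end}) outside the base sequence")
        for rate in (self.thermophile_substitution_rate, self.mesophile_substitution_rate):
            if not 0.0 <= rate < 1.0:
                raise ConfigError("substitution rates must lie in [0, 1)")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ConfigError("indel_rate must lie in [0, 1)")


def _pop_dataclass(data: dict, cls, label: str):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {label} keys: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {label} section: {exc}") from None


def load_run_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate an analysis config from YAML."""
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("analysis config must be a YAML mapping")
    raw = dict(raw)
    proteins_raw = raw.pop("proteins", None)
    if not isinstance(proteins_raw, list):
        raise ConfigError("config must list proteins")
    proteins = [
        _pop_dataclass(dict(p), ProteinEntry, "protein") for p in proteins_raw
    ]
    analysis = _pop_dataclass(dict(raw.pop("analysis", {}) or {}), AnalysisParams, "analysis")
    allowed = {"frame_interval_ps", "temperature_K", "output_dir"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(proteins=proteins, analysis=analysis, **raw)
    config.validate()
    return config


def load_generator_config(path: str | os.PathLike | None) -> GeneratorConfig:
    """Load a generator config from YAML (None gives pure defaults)."""
    if path is None:
        config = GeneratorConfig()
    else:
        with open(os.fspath(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("generator config must be a YAML mapping")
        if "regions" in raw:
            raw["regions"] = tuple(tuple(r) for r in raw["regions"])
        if "rigid_body_noise" in raw and isinstance(raw["rigid_body_noise"], dict):
            raw["rigid_body_noise"] = (
                raw["rigid_body_noise"].get("max_rotation_deg", 0.0),
                raw["rigid_body_noise"].get("max_translation_A", 0.0),
            )
        elif "rigid_body_noise" in raw:
            raw["rigid_body_noise"] = tuple(raw["rigid_body_noise"])
        config = _pop_dataclass(raw, GeneratorConfig, "generator")
    config.validate()
    return config
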
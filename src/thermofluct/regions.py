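"""Cross-homolog RMSF-difference profiles and high-fluctuation region calling.

The comparison statistic: on the common (alignment-column) numbering, the
per-column difference between the mesophile's RMSF and the mean RMSF of the
thermophiles.  Columns whose difference strictly exceeds the average
difference are flagged and merged into contiguous Regions (labelled I, II,
...), optionally bridging short unflagged stretches; runs shorter than a
minimum length are discarded.  Columns where any contributing protein has an
alignment gap carry no difference value and are excluded from both the
profile and the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import AlignmentMap
from .superpose import RMSFProfile

__all__ = [
    "DeltaProfile",
    "FluctuationRegion",
    "delta_profile",
    "detect_regions",
    "map_regions_to_proteins",
]


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = ""
    for value, sym in numerals:
        while n >= value:
            out += sym
            n -= value
    return out


@dataclass
class DeltaProfile:
    """Per-common-column RMSF difference (mesophile minus thermophile mean)."""

    common_columns: np.ndarray  # ascending, gap-free in all contributors
    delta: np.ndarray  # Angstrom
    contributing_proteins: tuple[str, ...]
    mean_delta: float

    def __post_init__(self) -> None:
        self.common_columns = np.asarray(self.common_columns, dtype=int)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.common_columns.shape != self.delta.shape:
            raise ValueError("columns and delta must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"common_column": self.common_columns, "delta_rmsf_A": self.delta}
        )


@dataclass
class FluctuationRegion:
    """A contiguous run of common columns with above-average RMSF difference."""

    label: str
    start_column: int
    end_column: int
    length: int
    mean_delta_in_region: float

    def __post_init__(self) -> None:
        if self.start_column > self.end_column:
            raise ValueError("region start must not exceed end")


def delta_profile(
    rmsf_profiles: dict[str, RMSFProfile],
    alignment_map: AlignmentMap,
    mesophile_id: str,
    thermophile_ids: list[str],
) -> DeltaProfile:
    """Mesophile-minus-mean(thermophiles) RMSF on the common numbering.

    Only columns gap-free in every contributing protein are retained;
    ``mean_delta`` is the arithmetic mean over those retained columns.
    """
    contributors = [mesophile_id, *thermophile_ids]
    for pid in contributors:
        if pid not in rmsf_profiles:
            raise KeyError(f"no RMSF profile for protein {pid!r}")
        if pid not in alignment_map.to_column:
            raise KeyError(f"protein {pid!r} missing from alignment map")
    values = {pid: rmsf_profiles[pid].as_dict() for pid in contributors}
    columns: list[int] = []
    deltas: list[float] = []
    for col in alignment_map.shared_columns(contributors):
        per_protein = {}
        for pid in contributors:
            residue = alignment_map.residue_for(pid, col)
            if residue is None or residue not in values[pid]:
                per_protein = None
                break
            per_protein[pid] = values[pid][residue]
        if per_protein is None:
            continue
        thermo_mean = float(np.mean([per_protein[t] for t in thermophile_ids]))
        columns.append(col)
        deltas.append(per_protein[mesophile_id] - thermo_mean)
    mean_delta = float(np.mean(deltas)) if deltas else 0.0
    return DeltaProfile(
        common_columns=np.array(columns, dtype=int),
        delta=np.array(deltas, dtype=float),
        contributing_proteins=tuple(contributors),
        mean_delta=mean_delta,
    )


def detect_regions(
    profile: DeltaProfile, min_length: int = 3, gap_tolerance: int = 2
) -> list[FluctuationRegion]:
    """Threshold-and-merge region calling on a difference profile.

    Columns with delta strictly above the profile mean are flagged; runs of
    flagged columns are merged across at most ``gap_tolerance`` consecutive
    unflagged columns; surviving runs of at least ``min_length`` columns are
    labelled I, II, ... in sequence order.  Run positions are indices into the
    retained-column list, so alignment-gap columns (absent from the profile)
    do not count toward the bridged stretch.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    n = len(profile.common_columns)
    if n == 0:
        return []
    flagged = profile.delta > profile.mean_delta  # strict: ties are not flagged
    runs: list[tuple[int, int]] = []  # inclusive index ranges of flagged runs
    start = None
    for i, f in enumerate(flagged):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= gap_tolerance:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    regions: list[FluctuationRegion] = []
    for lo, hi in merged:
        if hi - lo + 1 < min_length:
            continue
        member = profile.delta[lo : hi + 1]
        regions.append(
            FluctuationRegion(
                label=_roman(len(regions) + 1),
                start_column=int(profile.common_columns[lo]),
                end_column=int(profile.common_columns[hi]),
                length=hi - lo + 1,
                mean_delta_in_region=float(member.mean()),
            )
        )
    return regions


def map_regions_to_proteins(
    regions: list[FluctuationRegion], alignment_map: AlignmentMap
) -> dict[str, list[dict]]:
    """Translate regions into each protein's own residue numbering.

    For each protein and region the residues at the region's gap-free columns
    form the span; a region lying entirely in a protein's gaps yields an
    empty, flagged span.
    """
    out: dict[str, list[dict]] = {}
    for pid in alignment_map.ids:
        spans: list[dict] = []
        for region in regions:
            residues = [
                r
                for col in range(region.start_column, region.end_column + 1)
                if (r := alignment_map.residue_for(pid, col)) is not None
            ]
            spans.append(
                {
                    "label": region.label,
                    "start_residue": min(residues) if residues else None,
                    "end_residue": max(residues) if residues else None,
                    "n_residues": len(residues),
                    "all_gap": not residues,
                }
            )
        out[pid] = spans
    return out
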
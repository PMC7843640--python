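# Methods

## Data model

All coordinates are in Å, times in ps. A `Structure` is an ordered atom list
with author residue numbering (no renumbering on read); a `Trajectory` is a
frame stack over a fixed topology with a sampling interval. Multi-model PDB
is the on-disk trajectory format; the frame interval is not representable in
PDB and is supplied by configuration (default 400 ps). Frames are indexed
from t = interval (a 400 ns run at 400 ps yields exactly 1,000 frames).
Alternate-location indicators and insertion codes are rejected with a clear
error; HETATM records are ignored (ligand handling is out of scope).
Temperature is carried as metadata only.

## Superposition, RMSD, RMSF

Optimal rigid superposition uses the SVD form of the Kabsch algorithm with
the reflection branch suppressed (rotation determinant forced to +1);
degenerate inputs (< 3 points, collinear sets) are rejected. Weights default
to uniform. Per-frame RMSD superposes each frame independently onto the
reference (default: the trajectory's own reference structure, Cα selection).

RMSF uses a deterministic two-pass iterated-mean reference: frames are
superposed onto frame 1 and averaged, then re-superposed onto that mean and
re-averaged; RMSF_i is the RMS deviation of residue i's selected atom about
its final mean position. The selection must resolve to exactly one atom per
residue. No equilibration frames are discarded by default
(`burn_in_frames` is configurable).

**Estimator bias.** Fitting rotation + translation to every frame absorbs
six degrees of freedom of the noise. For N fitted atoms with isotropic
per-axis standard deviation σ the expectation is

  E[RMSF²] ≈ 3σ²·(1 − 2/N)·(1 − 1/n_frames),

not 3σ², and mean RMSD obeys the same (1 − 2/N) factor plus the usual
chi-distribution (Jensen) correction. The closed-form tests use these
finite-size expectations; at the sizes tested (N ≥ 60) the bias is below 2%
but would exceed naive per-residue 3·SE bands at large frame counts, which
is why profile-level assertions use the single-residue SE band around σ√3
and per-residue assertions use a simultaneous (Šidák-corrected) band around
the corrected expectation.

## Homolog mapping

Pairwise alignment is global (Needleman–Wunsch/Gotoh) with BLOSUM62 and
affine gaps: a gap of length L costs open + (L−1)·extend, defaults
open = 10, extend = 1. Tie-breaking is deterministic: on equal score a
diagonal step is preferred over a gap in the first sequence over a gap in
the second. The multiple alignment is progressive: the closest pair by
pairwise percent identity seeds a profile; remaining sequences join in order
of decreasing best identity to the included set (ties lexicographic by id)
and are aligned to the profile with column-average scoring (mean BLOSUM62
score over the column's non-gap residues).

The common residue numbering is simply the alignment column index; the map
records, per protein, residue ↔ column and the set of gap columns. Percent
identity counts identical residues over columns where neither sequence has
a gap — one of several conventions, recorded in the run metadata; published
"homology" percentages computed under unknown conventions are therefore not
claimed to be reproduced exactly. A structure's residue sequence must match
its FASTA record exactly, else the run aborts.

## Region calling

The difference profile is Δ(col) = RMSF_mesophile − mean over thermophiles,
computed only on columns gap-free in every contributing protein; the
threshold is the arithmetic mean of Δ over those retained columns (the
"average difference"). Columns with Δ strictly above the mean are flagged
(ties unflagged — a deterministic rule), flagged runs are merged across at
most `gap_tolerance` (default 2) consecutive unflagged columns, and runs
shorter than `min_length` (default 3) are discarded; survivors are labelled
I, II, … in sequence order. The defaults keep single-column noise spikes
from forming regions while preserving broad multi-residue regions; both are
configurable, as is comparing each thermophile separately instead of their
mean (by passing a single thermophile id). Regions are translated back into
each protein's own numbering by dropping that protein's gap columns; a
region falling entirely into a protein's gap yields an empty, flagged span.
Secondary-structure annotation of regions is accepted as user input, not
computed.

## Interactions

Criteria are distance-only over heavy atoms: no donor–H–acceptor angles
(the coarse topology carries no hydrogens; an angle term is a possible
extension). Salt bridges pair basic side-chain atoms (Lys NZ; Arg
NH1/NH2/NE; His ND1/NE2 — His treated as potentially basic, protonation out
of scope) with acidic ones (Asp OD1/OD2; Glu OE1/OE2); hydrogen bonds pair
any N/O heavy atoms, excluding intra-residue pairs and backbone–backbone
pairs of adjacent residues. Candidates are found on the reference structure
within a 6.0 Å search radius and reported once in canonical residue order.
Contact cutoffs are 4.0 Å (salt bridge) and 3.5 Å (hydrogen bond) — standard
literature heavy-atom values; symmetric side-chain atoms are treated as
equivalent via a per-frame minimum. Occupancy is the fraction of frames
within the cutoff (distances are rigid-motion invariant, so no superposition
is involved); an interaction is called formed at occupancy ≥ 0.1 (the
`presence_threshold`), otherwise NI — as is any homolog whose partner
residue cannot chemically form the contact (e.g. a basic residue replaced by
methionine). The cross-homolog table is keyed by (interaction kind, common
column pair); rows that cannot be mapped are flagged rather than dropped.

## Synthetic data

The generator emulates exactly the features the analysis consumes:

- **Topology** — two atoms per residue (Cα plus one named side-chain tip:
  NZ for Lys, NE for Arg, OD1 for Asp, OE1 for Glu, OG1 for Thr, …). The
  Arg tip is NE so that planted arginine bridges are visible to the
  salt-bridge search; glycine is excluded from the generator alphabet (no
  side chain to represent). Cα positions follow a self-avoiding random walk
  with 3.75–3.85 Å steps and mild spherical confinement.
- **Thermal noise** — independent per-frame Gaussian displacement per atom
  with that residue's per-axis σ; contiguous region overrides plant
  high-fluctuation regions.
- **Rigid-body noise** — each frame is additionally rotated (uniform axis,
  angle up to 5° by default) and translated (up to 1 Å per component), so
  superposition must do real work.
- **Planted contacts** — per frame, a contact's distance is set to its bound
  value with probability = occupancy (independent Bernoulli) and its unbound
  value otherwise, plus Gaussian jitter, by moving the partner atom along
  the current pair axis; the first atom (and every Cα) is untouched, keeping
  RMSF and interaction signals quasi-independent. Because a random walk does
  not bring arbitrary residue pairs close, the reference places the partner
  tip next to its counterpart (bound distance when occupancy > 0, unbound
  otherwise) regardless of its own Cα — a deliberate abstraction of the
  coarse topology.
- **Homolog sequences** — per-site substitutions and occasional
  single-residue indels with ground-truth correspondence returned for
  mapping tests; planted motif positions are exempt from mutation.

A single RNG stream per call, seeded explicitly, makes every output
deterministic; seeds are recorded in the ground-truth sidecar.

**Default study set** (`GeneratorConfig`): 1,000 frames at 400 ps (400 ns)
and 358 K metadata; thermophiles of 125 residues vs a 137-residue mesophile
(a 12-residue flexible C-terminal extension); substitution rates 0.25
(thermophile) and 0.5 (mesophile) giving ≈ 50% mesophile–thermophile
identity; baseline per-axis σ of 0.25 / 0.35 / 0.45 Å for hyperthermophile /
thermophile / mesophile (producing the rigidity ordering in overall RMSD)
with four planted mesophile regions at σ = 0.9 Å; and four interaction
motifs: K12–D82 (occupied in both thermophiles, lysine→methionine in the
mesophile), R25–E26 (strong only in the hyperthermophile), T36–T39 hydrogen
bond (strong only in the hyperthermophile) and R81–E90 (absent in the middle
thermophile).

**What passing tests do and do not show.** The generator produces harmonic,
uncorrelated, isotropic fluctuations and memoryless two-state contacts. Real
trajectories have anharmonic, correlated motions, drifting means, correlated
contact lifetimes and solvent effects; recovery of planted parameters here
validates the estimators' correctness, not their statistical efficiency on
real MD output. Published region boundaries and occupancies from any
specific study require that study's original trajectories and are out of
scope.

## Numerical choices and degenerate inputs

Superposition rejects collinear point sets (second singular value below
1e-8 of the first). A planted contact whose pair axis degenerates (zero
vector) falls back to a random direction. Region labels are Roman numerals
in column order. Ties at the region threshold are unflagged; ties in
alignment scoring follow the fixed step preference; progressive-order ties
are lexicographic. CSV outputs contain no timestamps so identical runs are
byte-identical (timestamps live only in `report.json`).

## Problem sizes

Default analyses run three proteins × 1,000 frames × ≈ 250 atoms in well
under a minute on one core. The closed-form RMSF check uses 300 residues ×
5,000 frames; region-recovery experiments use 125 residues × 1,000 frames
over 5 seeds; test-suite pipeline runs use 60–120 frames, which is ample for
the deterministic properties they check.
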
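"""Homolog sequence alignment and the shared residue numbering built from it.

Per-residue quantities (RMSF, interactions) can only be compared across
homologs of different lengths on a common coordinate system.  Here that
system is the column index of a global multiple alignment: pairwise
alignments use Gotoh affine-gap dynamic programming (BLOSUM62, gap open 10,
gap extend 1, a gap of length L costing open + (L-1)*extend), and the
multiple alignment is progressive — the closest pair (by pairwise identity)
is aligned first and each remaining sequence is aligned to the growing
profile with column-average scoring.  Tie-breaking is deterministic
throughout: on equal score a diagonal step is preferred over a gap in the
first sequence, which is preferred over a gap in the second; sequence
ordering ties fall back to lexicographic id.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

from Bio.Align import substitution_matrices

from .core import SequenceRecord, Structure

__all__ = [
    "AlignParams",
    "Alignment",
    "AlignmentMap",
    "align_pair",
    "align_many",
    "percent_identity",
    "build_map",
    "check_structure_sequence",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring parameters (dimensionless BLOSUM-style scores)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")


@lru_cache(maxsize=4)
def _score_table(matrix_name: str) -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load(matrix_name)
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


@dataclass
class Alignment:
    """A gapped global alignment: one equal-length row per sequence id."""

    ids: list[str]
    rows: list[str]
    score: float

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all alignment rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in alignment") from None

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


# traceback step codes, in tie-preference order:
# 0 = diagonal (match/mismatch), 1 = gap in A (consume B), 2 = gap in B
def _gotoh(
    cols_a: list,
    cols_b: list,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global alignment of two item lists; returns (score, path).

    The path is a list of (index_in_A, index_in_B) with -1 marking a gap.
    Items may be characters or profile columns; ``score_fn`` scores a pair.
    """
    n, m = len(cols_a), len(cols_b)
    # state matrices: M diagonal, X gap-in-A, Y gap-in-B
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr_m = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -gap_open - (j - 1) * gap_extend
        ptr_x[0][j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        Y[i][0] = -gap_open - (i - 1) * gap_extend
        ptr_y[i][0] = 0 if i == 1 else 2

    def _best(m_val: float, x_val: float, y_val: float) -> tuple[float, int]:
        # ties prefer M over X over Y
        if m_val >= x_val and m_val >= y_val:
            return m_val, 0
        if x_val >= y_val:
            return x_val, 1
        return y_val, 2

    for i in range(1, n + 1):
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = score_fn(cols_a[i - 1], cols_b[j - 1])
            best, which = _best(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            row_m[j] = best + s
            ptr_m[i][j] = which
            best, which = _best(
                row_m[j - 1] - gap_open,
                row_x[j - 1] - gap_extend,
                row_y[j - 1] - gap_open,
            )
            row_x[j] = best
            ptr_x[i][j] = which
            best, which = _best(
                prev_m[j] - gap_open,
                prev_x[j] - gap_open,
                prev_y[j] - gap_extend,
            )
            row_y[j] = best
            ptr_y[i][j] = which

    score, state = _best(M[n][m], X[n][m], Y[n][m])
    path: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            path.append((i - 1, j - 1))
            state = ptr_m[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((-1, j - 1))
            state = ptr_x[i][j]
            j -= 1
        else:
            path.append((i - 1, -1))
            state = ptr_y[i][j]
            i -= 1
    path.reverse()
    return score, path


def align_pair(
    seq_a: SequenceRecord, seq_b: SequenceRecord, params: AlignParams | None = None
) -> Alignment:
    """Global pairwise alignment (Gotoh affine-gap dynamic programming)."""
    params = params or AlignParams()
    if not seq_a.sequence or not seq_b.sequence:
        raise ValueError("cannot align empty sequences")
    table = _score_table(params.matrix)
    score, path = _gotoh(
        list(seq_a.sequence),
        list(seq_b.sequence),
        lambda a, b: table[(a, b)],
        params.gap_open,
        params.gap_extend,
    )
    row_a = "".join("-" if ia < 0 else seq_a.sequence[ia] for ia, _ in path)
    row_b = "".join("-" if ib < 0 else seq_b.sequence[ib] for _, ib in path)
    return Alignment(ids=[seq_a.id, seq_b.id], rows=[row_a, row_b], score=score)


def _profile_score_fn(table):
    def score(col_a: tuple, col_b: tuple) -> float:
        total, count = 0.0, 0
        for x in col_a:
            if x == "-":
                continue
            for y in col_b:
                if y == "-":
                    continue
                total += table[(x, y)]
                count += 1
        return total / count if count else 0.0

    return score


def align_many(
    seqs: list[SequenceRecord], params: AlignParams | None = None
) -> Alignment:
    """Progressive global multiple alignment.

    The most similar pair (pairwise percent identity; ties broken by
    lexicographic id pair) seeds the profile; remaining sequences join in
    order of decreasing best identity to an already-included sequence (ties
    lexicographic), each aligned to the profile with column-average scoring.
    The reported score is that of the final profile alignment step (the DP
    score for a plain pair).  Rows are returned in input order.
    """
    params = params or AlignParams()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("sequence ids must be unique")
    by_id = {s.id: s for s in seqs}
    if len(seqs) == 2:
        aln = align_pair(seqs[0], seqs[1], params)
        return aln

    identity: dict[tuple[str, str], float] = {}
    for a, b in combinations(seqs, 2):
        aln = align_pair(a, b, params)
        pid = percent_identity(aln, a.id, b.id)
        identity[(a.id, b.id)] = identity[(b.id, a.id)] = pid

    pairs = sorted(tuple(sorted((a.id, b.id))) for a, b in combinations(seqs, 2))
    seed_a, seed_b = max(pairs, key=lambda p: identity[p])  # stable: first on ties
    seed = align_pair(by_id[seed_a], by_id[seed_b], params)
    profile_ids = list(seed.ids)
    profile_rows = list(seed.rows)
    score = seed.score

    table = _score_table(params.matrix)
    score_fn = _profile_score_fn(table)
    remaining = [s.id for s in seqs if s.id not in profile_ids]
    while remaining:
        remaining.sort(
            key=lambda sid: (
                -max(identity[(sid, pid)] for pid in profile_ids),
                sid,
            )
        )
        nxt = remaining.pop(0)
        seq = by_id[nxt]
        cols = [tuple(r[c] for r in profile_rows) for c in range(len(profile_rows[0]))]
        score, path = _gotoh(
            cols, list(seq.sequence), score_fn, params.gap_open, params.gap_extend
        )
        new_rows = ["" for _ in profile_rows]
        new_row = ""
        for ia, ib in path:
            for k in range(len(profile_rows)):
                new_rows[k] += profile_rows[k][ia] if ia >= 0 else "-"
            new_row += seq.sequence[ib] if ib >= 0 else "-"
        profile_rows = new_rows + [new_row]
        profile_ids = profile_ids + [nxt]

    order = [s.id for s in seqs]
    rows = [profile_rows[profile_ids.index(sid)] for sid in order]
    return Alignment(ids=order, rows=rows, score=score)


def percent_identity(alignment: Alignment, id_a: str, id_b: str) -> float:
    """Percent identical residues over columns where neither id has a gap.

    The denominator excludes every gap column (one of several conventions;
    recorded in run metadata).  Reported to one decimal.
    """
    row_a, row_b = alignment.row(id_a), alignment.row(id_b)
    same = total = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        total += 1
        if x == y:
            same += 1
    if total == 0:
        return 0.0
    return round(100.0 * same / total, 1)


@dataclass
class AlignmentMap:
    """Residue numbering <-> common alignment column, per protein.

    Residues are numbered 1..len(sequence) in each protein's own numbering;
    columns are 1-based alignment column indices.  Columns where a protein
    has a gap are flagged in ``gap_columns``.
    """

    to_column: dict[str, dict[int, int]]
    to_residue: dict[str, dict[int, int]]
    gap_columns: dict[str, frozenset[int]]
    n_columns: int

    @property
    def ids(self) -> list[str]:
        return list(self.to_column)

    def column_for(self, seq_id: str, residue_number: int) -> int:
        return self.to_column[seq_id][residue_number]

    def residue_for(self, seq_id: str, column: int) -> int | None:
        """Residue at a column, or None where that protein has a gap."""
        return self.to_residue[seq_id].get(column)

    def shared_columns(self, ids: list[str] | None = None) -> list[int]:
        """Columns gap-free in every (given) protein, ascending."""
        ids = ids or self.ids
        gaps: set[int] = set()
        for sid in ids:
            gaps |= self.gap_columns[sid]
        return [c for c in range(1, self.n_columns + 1) if c not in gaps]


def build_map(alignment: Alignment) -> AlignmentMap:
    """Assign the common residue numbering: column index of each residue."""
    to_column: dict[str, dict[int, int]] = {}
    to_residue: dict[str, dict[int, int]] = {}
    gap_columns: dict[str, frozenset[int]] = {}
    for sid, row in zip(alignment.ids, alignment.rows):
        fwd: dict[int, int] = {}
        inv: dict[int, int] = {}
        gaps: set[int] = set()
        residue = 0
        for col, char in enumerate(row, start=1):
            if char == "-":
                gaps.add(col)
            else:
                residue += 1
                fwd[residue] = col
                inv[col] = residue
        to_column[sid] = fwd
        to_residue[sid] = inv
        gap_columns[sid] = frozenset(gaps)
    return AlignmentMap(
        to_column=to_column,
        to_residue=to_residue,
        gap_columns=gap_columns,
        n_columns=alignment.n_columns,
    )


def check_structure_sequence(structure: Structure, record: SequenceRecord) -> None:
    """Hard error if a structure's residue sequence differs from its record."""
    seq = structure.sequence()
    if seq != record.sequence:
        raise ValueError(
            f"structure {structure.name!r} sequence does not match record "
            f"{record.id!r}: {seq[:20]}... vs {record.sequence[:20]}..."
        )
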
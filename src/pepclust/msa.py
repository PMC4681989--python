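"""Per-cluster multiple sequence alignments and column statistics.

Cluster MSAs come from two constructions only: shift-based placement of
greedy-cluster members (:func:`core_msa`) and insertion of new rows
along a profile-HMM alignment path (:func:`insert_sequence`).  Columns
conserved enough (< 5 % gaps, information content >= 1.2 bits by
default) become the match states of the cluster's profile HMM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .substitution import AA_INDEX, AMINO_ACIDS

GAP = "-"


@dataclass
class MSA:
    """An alignment: rows of equal width over the residue alphabet + gaps."""

    rows: list[tuple[str, str]]  # (sequence id, aligned string)

    def __post_init__(self) -> None:
        if self.rows:
            w = len(self.rows[0][1])
            for rid, aligned in self.rows:
                if len(aligned) != w:
                    raise ValueError(f"row {rid!r} has width {len(aligned)} != {w}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, col: int) -> str:
        return "".join(aligned[col] for _, aligned in self.rows)

    def sequences(self) -> list[str]:
        """Degapped row sequences, in row order."""
        return [aligned.replace(GAP, "") for _, aligned in self.rows]

    def validate(self) -> None:
        """Assert structural invariants (equal widths, degap identity,
        no all-gap column)."""
        for rid, aligned in self.rows:
            if len(aligned) != self.width:
                raise AssertionError("ragged MSA")
            if aligned.replace(GAP, "") != rid:
                raise AssertionError(f"row {rid!r} does not degap to its id")
        for c in range(self.width):
            if all(ch == GAP for ch in self.column(c)):
                raise AssertionError(f"column {c} is all gaps")

    # -- column statistics --------------------------------------------------

    def gap_fraction(self, col: int) -> float:
        colstr = self.column(col)
        return colstr.count(GAP) / len(colstr)

    def residue_frequencies(self, col: int) -> np.ndarray:
        """Frequencies of the 20 residues among non-gap entries of *col*."""
        counts = np.zeros(20)
        for ch in self.column(col):
            if ch != GAP:
                counts[AA_INDEX[ch]] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError(f"column {col} is all gaps")
        return counts / total

    def consensus(self) -> str:
        """Majority residue of every column shown in logos (< 50 % gaps)."""
        out = []
        for c in range(self.width):
            if self.gap_fraction(c) < 0.5:
                freqs = self.residue_frequencies(c)
                out.append(AMINO_ACIDS[int(freqs.argmax())])
        return "".join(out)


@dataclass(frozen=True)
class ColumnStats:
    """Summary of one MSA column."""

    column: int
    gap_fraction: float
    information_content: float
    residue_frequencies: np.ndarray = field(repr=False)


def column_information_content(msa: MSA, col: int) -> float:
    """Information content of a column in bits: ``log2(20) - H``.

    ``H`` is the Shannon entropy of the non-gap residue distribution.
    No small-sample correction or background weighting is applied.
    """
    freqs = msa.residue_frequencies(col)
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return math.log2(20) - entropy


def column_stats(msa: MSA, col: int) -> ColumnStats:
    return ColumnStats(
        column=col,
        gap_fraction=msa.gap_fraction(col),
        information_content=column_information_content(msa, col),
        residue_frequencies=msa.residue_frequencies(col),
    )


def match_columns(msa: MSA, gap_threshold: float = 0.05,
                  ic_threshold: float = 1.2) -> list[int]:
    """Columns qualifying as profile-HMM match states.

    A column qualifies when its gap fraction is strictly below
    *gap_threshold* and its information content is at least
    *ic_threshold* bits.
    """
    out = []
    for c in range(msa.width):
        if msa.gap_fraction(c) < gap_threshold \
                and column_information_content(msa, c) >= ic_threshold:
            out.append(c)
    return out


def inner_gap_count(msa: MSA) -> int:
    """Total gaps flanked by residues on both sides within their row."""
    total = 0
    for _, aligned in msa.rows:
        stripped = aligned.strip(GAP)
        total += stripped.count(GAP)
    return total


def logo_frequencies(msa: MSA) -> list[ColumnStats]:
    """Column statistics for logo display: columns with < 50 % gaps."""
    return [column_stats(msa, c) for c in range(msa.width)
            if msa.gap_fraction(c) < 0.5]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def core_msa(cluster) -> MSA:
    """Build a cluster-core MSA from stored greedy shift alignments.

    Members are padded with leading/trailing gaps according to their
    shift against the representative; no inner gaps are introduced.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    # member b with shift s occupies representative coordinates [s, s+len-1]
    starts = [aln.shift for _, aln in cluster.members]
    ends = [aln.shift + len(seq.sequence) - 1 for seq, aln in cluster.members]
    lo, hi = min(starts), max(ends)
    width = hi - lo + 1
    rows = []
    for seq, aln in cluster.members:
        left = aln.shift - lo
        right = width - left - len(seq.sequence)
        rows.append((seq.sequence, GAP * left + seq.sequence + GAP * right))
    return MSA(rows)


def insert_sequence(msa: MSA, sequence: str, hit,
                    match_column_map: list[int]) -> MSA:
    """Add one sequence to *msa* along its profile-HMM alignment path.

    Match-state residues land in the existing match columns
    (*match_column_map* maps match-state index -> MSA column); each
    insert-state residue opens a fresh column that is all-gap in every
    other row; delete states leave gaps.  Flanking residues outside the
    local alignment span fill the existing columns adjacent to the
    aligned region and overflow into new edge columns.  Existing rows
    keep their residue content unchanged.
    """
    return insert_sequence_mapped(msa, sequence, hit, match_column_map)[0]


def insert_sequence_mapped(
    msa: MSA, sequence: str, hit, match_column_map: list[int],
) -> tuple[MSA, list[int]]:
    """:func:`insert_sequence` plus the old-column -> new-column map.

    The map lets callers renumber match columns after columns are
    opened by inserts or flank overflow.
    """
    W = msa.width
    placed: dict[int, str] = {}          # existing column -> residue
    # new columns: anchor -> list of residues; anchor -1 = left edge,
    # anchor c = immediately after existing column c
    new_cols: dict[int, list[str]] = {}

    path = hit.path
    if not path or path[0][0] != "M" or path[-1][0] != "M":
        raise ValueError("alignment path must start and end in a match state")

    first_k = path[0][1]
    last_k = path[-1][1]
    start, end = hit.span

    for op, k, i in path:
        if op == "M":
            col = match_column_map[k]
            if col in placed:
                raise ValueError("path visits a match column twice")
            placed[col] = sequence[i]
        elif op == "I":
            new_cols.setdefault(match_column_map[k], []).append(sequence[i])
        elif op == "D":
            pass  # gap in the new row at match_column_map[k]
        else:  # pragma: no cover
            raise ValueError(f"unknown path op {op!r}")

    # left flank: right-aligned into columns left of the first aligned column
    first_col = match_column_map[first_k]
    overflow_left: list[str] = []
    for j in range(start):            # residues sequence[0:start]
        col = first_col - (start - j)
        if col >= 0:
            placed[col] = sequence[j]
        else:
            overflow_left.append(sequence[j])
    if overflow_left:
        new_cols.setdefault(-1, [])
        new_cols[-1] = overflow_left + new_cols[-1]

    # right flank: left-aligned into columns right of the last aligned column
    last_col = match_column_map[last_k]
    n_right = len(sequence) - end
    overflow_right: list[str] = []
    for j in range(n_right):          # residues sequence[end:]
        col = last_col + 1 + j
        if col < W:
            if col in placed:
                raise ValueError("flank collides with aligned residue")
            placed[col] = sequence[end + j]
        else:
            overflow_right.append(sequence[end + j])
    if overflow_right:
        new_cols.setdefault(W - 1, []).extend(overflow_right)

    # rebuild all rows with the new column layout
    def build(old_row: str | None, is_new: bool) -> str:
        out: list[str] = []
        for res in new_cols.get(-1, []):
            out.append(res if is_new else GAP)
        for c in range(W):
            if is_new:
                out.append(placed.get(c, GAP))
            else:
                out.append(old_row[c])  # type: ignore[index]
            for res in new_cols.get(c, []):
                out.append(res if is_new else GAP)
        return "".join(out)

    rows = [(rid, build(aligned, False)) for rid, aligned in msa.rows]
    new_aligned = build(None, True)
    if new_aligned.replace(GAP, "") != sequence:
        raise AssertionError("inserted row does not degap to its sequence")
    rows.append((sequence, new_aligned))

    col_map: list[int] = []
    pos = len(new_cols.get(-1, []))
    for c in range(W):
        col_map.append(pos)
        pos += 1 + len(new_cols.get(c, []))
    return MSA(rows), col_map
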
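"""Inner-gap-free, shift-limited pairwise peptide scoring.

Greedy seeding compares short peptides with a deliberately restricted
alignment: no inner gaps, only a relative shift of one sequence against
the other, bounded by ``max_shift`` trailing-gap positions on either
end.  Overhanging (trailing) positions score zero; the score is the sum
of substitution-matrix entries over the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .substitution import AA_INDEX, SubstitutionMatrix


@dataclass(frozen=True)
class ShiftAlignment:
    """Best shift-limited gapless alignment of ``b`` against ``a``.

    ``shift`` is the offset of ``b`` relative to ``a``: residue ``b[i]``
    is paired with ``a[i + shift]``.  Positive shift slides ``b`` left
    (b starts before a); negative slides it right.
    """

    score: int
    shift: int
    overlap_length: int


def gapless_shift_score(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    max_shift: int = 1,
) -> ShiftAlignment:
    """Score ``a`` vs ``b`` over all shifts in ``[-max_shift, +max_shift]``.

    Returns the shift maximizing the summed matrix score over the
    overlapping residue pairs.  Ties prefer the smaller ``|shift|``,
    then the negative shift.

    Raises
    ------
    ValueError
        If either peptide is empty, or ``max_shift`` is so large that
        some shift would leave an empty overlap.
    """
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    if max_shift < 0:
        raise ValueError("max_shift must be non-negative")
    if max_shift >= min(len(a), len(b)):
        raise ValueError(
            f"max_shift {max_shift} leaves no overlap for lengths "
            f"{len(a)}, {len(b)}")

    scores = matrix.scores
    ai = [AA_INDEX[c] for c in a]
    bi = [AA_INDEX[c] for c in b]

    best: ShiftAlignment | None = None
    # enumerate shifts in tie-break priority order: |s| ascending, negative first
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        # b[i] pairs with a[i + s]
        lo = max(0, -s)                      # first valid i
        hi = min(len(b), len(a) - s)         # one past last valid i
        if hi <= lo:
            continue
        total = 0
        for i in range(lo, hi):
            total += scores[ai[i + s], bi[i]]
        if best is None or total > best.score:
            best = ShiftAlignment(int(total), s, hi - lo)
    assert best is not None
    return best
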
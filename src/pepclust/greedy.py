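"""Initial greedy incremental clustering and cluster-core selection.

A single pass over sorted sequences: the first sequence founds the
first cluster; every subsequent sequence either joins the cluster whose
representative it matches best (if that score reaches the threshold) or
founds a new cluster.  Afterwards only the largest clusters are kept as
"cores" for profile-HMM extension; every other sequence enters the
sequence pool.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .pairwise import ShiftAlignment, gapless_shift_score
from .seqio import UniqueSequence
from .substitution import SubstitutionMatrix

SORT_ORDERS = ("copy_number", "alphabetic", "random")


@dataclass
class GreedyCluster:
    """A representative plus members aligned to it by shift."""

    id: int
    representative: UniqueSequence
    members: list[tuple[UniqueSequence, ShiftAlignment]] = field(default_factory=list)

    @property
    def size_unique(self) -> int:
        return len(self.members)

    @property
    def size_total(self) -> int:
        return sum(m.total_count for m, _ in self.members)


@dataclass
class SequencePool:
    """Sequences not currently assigned to any selected cluster."""

    sequences: dict[str, UniqueSequence] = field(default_factory=dict)

    def add(self, seq: UniqueSequence) -> None:
        self.sequences[seq.sequence] = seq

    def remove(self, sequence: str) -> UniqueSequence:
        return self.sequences.pop(sequence)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.sequences

    def __iter__(self):
        return iter(self.sequences.values())


def sort_unique(
    sequences: list[UniqueSequence],
    order: str = "copy_number",
    seed: int = 0,
) -> list[UniqueSequence]:
    """Order sequences for the greedy pass.

    ``copy_number`` sorts by total copy count descending (ties broken
    alphabetically ascending), ``alphabetic`` lexicographically, and
    ``random`` shuffles reproducibly with *seed*.
    """
    if order == "copy_number":
        return sorted(sequences, key=lambda u: (-u.total_count, u.sequence))
    if order == "alphabetic":
        return sorted(sequences, key=lambda u: u.sequence)
    if order == "random":
        out = list(sequences)
        random.Random(seed).shuffle(out)
        return out
    raise ValueError(f"unknown sort order {order!r}; expected one of {SORT_ORDERS}")


def greedy_cluster(
    ordered: list[UniqueSequence],
    matrix: SubstitutionMatrix,
    threshold: int,
    max_shift: int = 1,
) -> list[GreedyCluster]:
    """Single-pass greedy clustering against fixed representatives.

    Each sequence joins the best-scoring representative when that best
    score reaches *threshold*; equal best scores go to the
    earliest-created cluster.  Representatives never change.
    """
    if not ordered:
        raise ValueError("no sequences to cluster")

    clusters: list[GreedyCluster] = []
    for seq in ordered:
        best_cluster: GreedyCluster | None = None
        best_aln: ShiftAlignment | None = None
        for cl in clusters:
            aln = gapless_shift_score(
                cl.representative.sequence, seq.sequence, matrix, max_shift)
            if best_aln is None or aln.score > best_aln.score:
                best_cluster, best_aln = cl, aln
        if best_aln is not None and best_aln.score >= threshold:
            assert best_cluster is not None
            best_cluster.members.append((seq, best_aln))
        else:
            cl = GreedyCluster(id=len(clusters), representative=seq)
            cl.members.append((seq, ShiftAlignment(score=_self_score(seq, matrix),
                                                   shift=0,
                                                   overlap_length=len(seq))))
            clusters.append(cl)
    return clusters


def _self_score(seq: UniqueSequence, matrix: SubstitutionMatrix) -> int:
    return sum(matrix.score(c, c) for c in seq.sequence)


def default_greedy_threshold(sequences: list[UniqueSequence],
                             per_residue: float = 2.0) -> int:
    """Absolute greedy threshold scaled to the data: ``round(theta * L)``
    with ``L`` the median sequence length."""
    lengths = sorted(len(s) for s in sequences)
    median = lengths[len(lengths) // 2]
    return round(per_residue * median)


def select_cores(
    clusters: list[GreedyCluster],
    fraction: float = 0.025,
    max_count: int = 250,
    min_size: int = 2,
) -> tuple[list[GreedyCluster], SequencePool]:
    """Keep the largest greedy clusters as cores; pool the rest.

    Clusters are ranked by unique-member count descending (ties: total
    copy count descending, then id ascending); the top
    ``min(max_count, ceil(fraction * n_clusters))`` with at least
    *min_size* unique members become cores.  Sequences of all other
    clusters are dissolved into the returned pool.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ranked = sorted(clusters,
                    key=lambda c: (-c.size_unique, -c.size_total, c.id))
    quota = min(max_count, math.ceil(fraction * len(clusters)))
    cores = [c for c in ranked[:quota] if c.size_unique >= min_size]

    core_ids = {c.id for c in cores}
    pool = SequencePool()
    for cl in clusters:
        if cl.id not in core_ids:
            for seq, _ in cl.members:
                pool.add(seq)
    return cores, pool
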
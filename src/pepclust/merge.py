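"""Cluster–cluster comparison and agglomerative merging.

Whole clusters are compared by a local alignment of their profile HMMs'
match states under a co-emission log-sum-of-odds column score, with
affine gap penalties.  Above-threshold pairs drive a best-first
agglomeration (a priority queue with lazy deletion); a heuristic
variant first partitions clusters into groups of potentially similar
clusters — connected components of the graph whose edges join clusters
with overlapping distant-hit sets — and agglomerates within groups
only.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

from .cluster import Cluster
from .msa import GAP, MSA

#: Affine gap penalties for HMM–HMM alignment, in bits.
GAP_OPEN = -3.0
GAP_EXTEND = -0.5


def hmm_hmm_score(a, b, gap_open: float = GAP_OPEN,
                  gap_extend: float = GAP_EXTEND):
    """Local alignment score of two profile HMMs over their match states.

    The column score is the co-emission log-sum-of-odds
    ``s(i, j) = log2( sum_r P_a,i(r) P_b,j(r) / bg(r) )`` — positive
    when the two states prefer the same residues more than background
    chance predicts.  Alignment is Smith–Waterman-style local with
    affine gaps.

    Returns ``(score, pairing)`` where pairing lists the aligned
    match-state index pairs ``(i_in_a, j_in_b)``.
    """
    Pa, Pb = a.match_emissions, b.match_emissions
    bg = a.background
    S = np.log2(Pa @ (Pb / bg[None, :]).T)  # (na, nb)
    na, nb = S.shape

    M = np.zeros((na + 1, nb + 1))
    Ix = np.full((na + 1, nb + 1), -np.inf)
    Iy = np.full((na + 1, nb + 1), -np.inf)
    ptr = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0 stop,1 diagM,2 diagIx,3 diagIy

    best, best_cell = 0.0, None
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            opts = (0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(opts))
            val = S[i - 1, j - 1] + opts[k]
            if val < 0.0:
                k, val = 0, 0.0
            M[i, j] = val
            ptr[i, j] = k
            if val > best:
                best, best_cell = val, (i, j)

    pairing: list[tuple[int, int]] = []
    if best_cell is not None:
        i, j = best_cell
        state = "M"
        while i > 0 and j > 0:
            if state == "M":
                pairing.append((i - 1, j - 1))
                p = ptr[i, j]
                if p == 0:
                    break
                state = {1: "M", 2: "Ix", 3: "Iy"}[int(p)]
                i, j = i - 1, j - 1
            elif state == "Ix":
                # came down column j: find run start greedily
                if M[i - 1, j] + gap_open >= Ix[i - 1, j] + gap_extend:
                    state = "M"
                i -= 1
            else:  # Iy
                if M[i, j - 1] + gap_open >= Iy[i, j - 1] + gap_extend:
                    state = "M"
                j -= 1
        pairing.reverse()
    return float(best), pairing


def merge_clusters(a: Cluster, b: Cluster, pairing, new_id: int,
                   rebuild_hmm=None) -> Cluster:
    """Merge *b* into *a* along an HMM–HMM match-state pairing.

    Paired match columns coincide in the merged MSA; between (and
    outside) the anchor pairs, *b*'s columns are overlaid positionally
    onto *a*'s — interior segments left-aligned, the left flank
    right-aligned and the right flank left-aligned — so only the excess
    columns of the wider side become gap columns for the other side's
    rows.  Every row still degaps to its original sequence.
    """
    if not pairing:
        raise ValueError("cannot merge clusters with an empty pairing")
    amap, bmap = a.hmm.match_column_map, b.hmm.match_column_map
    anchors = [(amap[i], bmap[j]) for i, j in pairing]

    def overlay(acols: range, bcols: range, align: str
                ) -> list[tuple[int | None, int | None]]:
        ka, kb = len(acols), len(bcols)
        n = max(ka, kb)
        seg: list[tuple[int | None, int | None]] = []
        for t in range(n):
            if align == "right":  # pad the shorter side on the left
                ia = t - (n - ka)
                ib = t - (n - kb)
            else:
                ia, ib = t, t
            seg.append((acols[ia] if 0 <= ia < ka else None,
                        bcols[ib] if 0 <= ib < kb else None))
        return seg

    cols: list[tuple[int | None, int | None]] = []
    pa = pb = 0
    for idx, (ca, cb) in enumerate(anchors):
        cols += overlay(range(pa, ca), range(pb, cb),
                        "right" if idx == 0 else "left")
        cols.append((ca, cb))
        pa, pb = ca + 1, cb + 1
    cols += overlay(range(pa, a.msa.width), range(pb, b.msa.width), "left")

    rows = []
    for rid, aligned in a.msa.rows:
        rows.append((rid, "".join(aligned[ca] if ca is not None else GAP
                                  for ca, _ in cols)))
    for rid, aligned in b.msa.rows:
        rows.append((rid, "".join(aligned[cb] if cb is not None else GAP
                                  for _, cb in cols)))
    merged_msa = MSA(rows)
    merged = Cluster(
        id=new_id,
        msa=merged_msa,
        members=a.members + b.members,
        provenance=a.provenance + b.provenance + [f"merge({a.id},{b.id})"],
    )
    if rebuild_hmm is not None:
        merged.hmm = rebuild_hmm(merged_msa)
    return merged


@dataclass
class MergeQueue:
    """Above-threshold cluster pairs, best first, with lazy deletion.

    Ties in score break toward the lexicographically smallest
    ``(min id, max id)`` pair so agglomeration order is deterministic.
    """

    _heap: list = field(default_factory=list)
    retired: set[int] = field(default_factory=set)

    def push(self, score: float, id_a: int, id_b: int) -> None:
        lo, hi = min(id_a, id_b), max(id_a, id_b)
        heapq.heappush(self._heap, (-score, lo, hi))

    def pop_live(self) -> tuple[float, int, int] | None:
        """Best pair whose clusters are both still live, or None."""
        while self._heap:
            neg, lo, hi = heapq.heappop(self._heap)
            if lo in self.retired or hi in self.retired:
                continue
            return -neg, lo, hi
        return None

    def retire(self, cid: int) -> None:
        self.retired.add(cid)


def _effective_threshold(threshold: float, a: Cluster, b: Cluster,
                         per_state: bool) -> float:
    if not per_state:
        return threshold
    return threshold * min(a.hmm.n_match, b.hmm.n_match)


def hierarchical_merge(
    clusters: list[Cluster],
    threshold: float,
    rebuild_hmm,
    diversity_ok=None,
    per_state: bool = True,
    id_counter=None,
) -> list[Cluster]:
    """Best-first agglomeration until no above-threshold pair remains.

    All-vs-all HMM–HMM scores seed the queue; repeatedly the highest
    scoring live pair is merged, the merged cluster is rescored against
    all survivors, and new above-threshold pairs are queued.  A merge
    whose result would violate the diversity constraints is skipped and
    that pair permanently discarded.  With *per_state* the threshold is
    scaled by the smaller model's match-state count.

    Guarantees on termination: every surviving pair either scores below
    threshold or was constraint-rejected.
    """
    live: dict[int, Cluster] = {c.id: c for c in sorted(clusters, key=lambda c: c.id)}
    if id_counter is None:
        id_counter = itertools.count(max(live, default=0) + 1)
    queue = MergeQueue()
    pairings: dict[tuple[int, int], list] = {}

    ids = sorted(live)
    for i, ai in enumerate(ids):
        for bj in ids[i + 1:]:
            a, b = live[ai], live[bj]
            score, pairing = hmm_hmm_score(a.hmm, b.hmm)
            if pairing and score >= _effective_threshold(threshold, a, b, per_state):
                queue.push(score, ai, bj)
                pairings[(ai, bj)] = pairing

    while True:
        item = queue.pop_live()
        if item is None:
            break
        _, lo, hi = item
        a, b = live[lo], live[hi]
        merged = merge_clusters(a, b, pairings[(lo, hi)], next(id_counter),
                                rebuild_hmm=None)
        if diversity_ok is not None and not diversity_ok(merged.msa):
            continue  # constraint-rejected pair: discard permanently
        merged.hmm = rebuild_hmm(merged.msa)
        queue.retire(lo)
        queue.retire(hi)
        del live[lo], live[hi]
        for cid in sorted(live):
            other = live[cid]
            score, pairing = hmm_hmm_score(merged.hmm, other.hmm)
            if pairing and score >= _effective_threshold(
                    threshold, merged, other, per_state):
                queue.push(score, merged.id, cid)
                pairings[(min(merged.id, cid), max(merged.id, cid))] = (
                    pairing if merged.id < cid
                    else [(j, i) for i, j in pairing])
        live[merged.id] = merged
    return [live[cid] for cid in sorted(live)]


def similarity_groups(distant_hit_sets: dict[int, set[str]]) -> list[set[int]]:
    """Connected components of the direct-similarity graph.

    Clusters are directly similar when their distant-hit sets overlap;
    groups are the transitive closure (union–find).  Clusters with
    empty hit sets form singleton groups.
    """
    parent = {cid: cid for cid in distant_hit_sets}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_seq: dict[str, int] = {}
    for cid in sorted(distant_hit_sets):
        for seq in distant_hit_sets[cid]:
            if seq in by_seq:
                union(by_seq[seq], cid)
            else:
                by_seq[seq] = cid

    groups: dict[int, set[int]] = {}
    for cid in distant_hit_sets:
        groups.setdefault(find(cid), set()).add(cid)
    return [groups[r] for r in sorted(groups)]


def heuristic_merge(
    clusters: list[Cluster],
    distant_hit_sets: dict[int, set[str]],
    threshold: float,
    rebuild_hmm,
    diversity_ok=None,
    per_state: bool = True,
) -> list[Cluster]:
    """Agglomerate independently within each group of potentially
    similar clusters.

    Exactly :func:`hierarchical_merge` restricted to each similarity
    group; singleton groups incur no HMM–HMM comparisons.  May merge
    fewer pairs than the full routine (never more).
    """
    by_id = {c.id: c for c in clusters}
    hit_sets = {c.id: distant_hit_sets.get(c.id, set()) for c in clusters}
    id_counter = itertools.count(max(by_id, default=0) + 1)
    out: list[Cluster] = []
    for group in similarity_groups(hit_sets):
        members = [by_id[cid] for cid in sorted(group)]
        if len(members) == 1:
            out.extend(members)
        else:
            out.extend(hierarchical_merge(
                members, threshold, rebuild_hmm, diversity_ok,
                per_state=per_state, id_counter=id_counter))
    return sorted(out, key=lambda c: c.id)
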
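"""The progressive cluster-growth pipeline.

Order of operations: deduplicated input -> greedy seeding -> core
selection -> for each of ``n_rounds`` rounds, a cluster-extension step
(pool sequences join the best-scoring cluster) followed by a merging
step (heuristic group-wise agglomeration, except the last round which
runs the complete agglomeration).  Similarity thresholds relax from
round to round so motifs emerge progressively, and every insertion or
merge is vetoed if it would make a cluster too diverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import greedy as _greedy
from . import merge as _merge
from . import msa as _msa
from . import phmm as _phmm
from .cluster import Cluster
from .seqio import UniqueSequence
from .substitution import SubstitutionMatrix, blosum62, blosum62_background


@dataclass
class RunConfig:
    """All pipeline knobs with their defaults.

    Thresholds are bits per match state, so relaxation schedules are
    independent of model size; ``extension_thresholds`` and
    ``merge_thresholds`` must be non-increasing, one entry per round.
    """

    n_rounds: int = 3
    extension_thresholds: tuple[float, ...] = (2.0, 1.5, 1.0)
    merge_thresholds: tuple[float, ...] = (1.5, 1.0, 0.5)
    distant_threshold_offset: float = 0.5

    # greedy seeding
    order: str = "copy_number"
    greedy_threshold: int | None = None       # None: round(per_residue * median L)
    greedy_per_residue: float = 2.0
    max_shift: int = 1

    # core selection
    core_fraction: float = 0.025
    core_max: int = 250
    core_min_size: int = 2

    # diversity control
    min_match_states: int = 4
    gap_threshold: float = 0.05
    ic_threshold: float = 1.2
    max_positions: int | None = None          # None: max input length + 4
    max_inner_gaps: int | None = None         # None: round(0.2 * n_rows)

    pseudocount_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("extension_thresholds", "merge_thresholds"):
            t = getattr(self, name)
            if len(t) != self.n_rounds:
                raise ValueError(f"{name} must have one entry per round")
            if any(a < b for a, b in zip(t, t[1:])):
                raise ValueError(f"{name} must be non-increasing")
        if self.n_rounds < 1:
            raise ValueError("need at least one round")
        if self.min_match_states < 1:
            raise ValueError("min_match_states must be positive")


@dataclass
class RunResult:
    """Final clusters, unassigned sequences, and the per-round log."""

    clusters: list[Cluster]
    unassigned: list[UniqueSequence]
    log: list[dict] = field(default_factory=list)

    def validate(self, input_sequences: list[UniqueSequence]) -> None:
        """Assert the partition invariant and per-cluster integrity."""
        seen: list[str] = [m.sequence for c in self.clusters for m in c.members]
        seen += [u.sequence for u in self.unassigned]
        if sorted(seen) != sorted(u.sequence for u in input_sequences):
            raise AssertionError("clusters + unassigned do not partition input")
        for c in self.clusters:
            c.validate()


def diversity_ok(candidate_msa: _msa.MSA, config: RunConfig) -> bool:
    """Would this MSA still describe an acceptably tight cluster?

    True iff it retains at least ``min_match_states`` match columns,
    its width does not exceed ``max_positions`` and its inner-gap count
    does not exceed ``max_inner_gaps`` (inclusive bounds).
    """
    mcols = _msa.match_columns(candidate_msa, config.gap_threshold,
                               config.ic_threshold)
    if len(mcols) < config.min_match_states:
        return False
    if config.max_positions is not None \
            and candidate_msa.width > config.max_positions:
        return False
    cap = config.max_inner_gaps
    if cap is None:
        cap = round(0.2 * candidate_msa.n_rows)
    return _msa.inner_gap_count(candidate_msa) <= cap


def _make_rebuild(config: RunConfig, background: np.ndarray):
    def rebuild(msa: _msa.MSA):
        mcols = _msa.match_columns(msa, config.gap_threshold, config.ic_threshold)
        return _phmm.build_phmm(msa, mcols,
                                pseudocount_weight=config.pseudocount_weight,
                                background=background,
                                min_match=config.min_match_states)
    return rebuild


def extension_round(
    clusters: list[Cluster],
    pool: _greedy.SequencePool,
    threshold: float,
    config: RunConfig,
    background: np.ndarray | None = None,
) -> tuple[list[Cluster], _greedy.SequencePool, dict[int, set[str]]]:
    """One cluster-extension step.

    Every pool sequence is scored against every cluster HMM; it is
    assigned to the cluster giving its highest bit score among those
    reaching ``threshold * n_match`` bits (ties: larger cluster, then
    smaller id).  Assigned sequences are inserted into the winner's MSA
    in descending score order, each insertion vetoed by
    :func:`diversity_ok`; vetoed sequences stay in the pool.  HMMs are
    rebuilt once per modified cluster at the end of the step.

    Also returns each cluster's distant-hit set (sequences reaching the
    lower threshold ``(threshold - distant_threshold_offset) * n_match``),
    reused by the heuristic merge.
    """
    if background is None:
        background = blosum62_background()
    pool_seqs = sorted(s.sequence for s in pool)
    distant_sets: dict[int, set[str]] = {c.id: set() for c in clusters}
    if not clusters or not pool_seqs:
        return clusters, pool, distant_sets

    clusters = sorted(clusters, key=lambda c: c.id)
    scores = np.full((len(clusters), len(pool_seqs)), -np.inf)
    for ci, cl in enumerate(clusters):
        scores[ci] = _phmm.score_sequences(cl.hmm, pool_seqs)
        distant = (threshold - config.distant_threshold_offset) * cl.hmm.n_match
        distant_sets[cl.id] = {s for s, sc in zip(pool_seqs, scores[ci])
                               if sc >= distant}

    # choose each sequence's cluster
    assigned: dict[int, list[tuple[float, str]]] = {c.id: [] for c in clusters}
    for si, seq in enumerate(pool_seqs):
        best = None  # (score, cluster index)
        for ci, cl in enumerate(clusters):
            sc = scores[ci, si]
            if sc < threshold * cl.hmm.n_match:
                continue
            if best is None:
                best = (sc, ci)
            else:
                bsc, bci = best
                if sc > bsc or (sc == bsc and (
                        clusters[ci].size_unique > clusters[bci].size_unique
                        or (clusters[ci].size_unique == clusters[bci].size_unique
                            and clusters[ci].id < clusters[bci].id))):
                    best = (sc, ci)
        if best is not None:
            assigned[clusters[best[1]].id].append((best[0], seq))

    rebuild = _make_rebuild(config, background)
    for cl in clusters:
        todo = sorted(assigned[cl.id], key=lambda t: (-t[0], t[1]))
        if not todo:
            continue
        col_map = list(cl.hmm.match_column_map)
        modified = False
        for _, seq in todo:
            hit = _phmm.viterbi_local(cl.hmm, seq)
            candidate, new_map = _msa.insert_sequence_mapped(
                cl.msa, seq, hit, col_map)
            if not diversity_ok(candidate, config):
                continue  # vetoed: sequence stays in the pool
            cl.msa = candidate
            col_map = [new_map[c] for c in col_map]
            cl.members.append(pool.remove(seq))
            cl.provenance.append(f"extend(+{seq})")
            modified = True
        if modified:
            cl.hmm = rebuild(cl.msa)
    return clusters, pool, distant_sets


def run(data: list[UniqueSequence], config: RunConfig | None = None,
        matrix: SubstitutionMatrix | None = None,
        background: np.ndarray | None = None) -> RunResult:
    """Run the full progressive clustering pipeline on unique sequences.

    Returns the final clusters and the unassigned remainder; the two
    always partition the input.  Deterministic for a given config.
    """
    if not data:
        raise ValueError("input is empty")
    config = config or RunConfig()
    config.validate()
    if matrix is None:
        matrix = blosum62()
    if background is None:
        background = blosum62_background()
    if config.max_positions is None:
        config = replace(config,
                         max_positions=max(len(u) for u in data) + 4)

    log: list[dict] = []
    ordered = _greedy.sort_unique(data, config.order, config.seed)
    thr = config.greedy_threshold
    if thr is None:
        thr = _greedy.default_greedy_threshold(data, config.greedy_per_residue)
    gclusters = _greedy.greedy_cluster(ordered, matrix, thr, config.max_shift)
    cores, pool = _greedy.select_cores(
        gclusters, config.core_fraction, config.core_max, config.core_min_size)
    log.append({"stage": "greedy", "n_greedy_clusters": len(gclusters),
                "greedy_threshold": thr, "n_cores": len(cores)})

    rebuild = _make_rebuild(config, background)
    clusters: list[Cluster] = []
    next_id = 0
    for core in cores:
        msa = _msa.core_msa(core)
        if diversity_ok(msa, config):
            cl = Cluster(id=next_id, msa=msa,
                         members=[seq for seq, _ in core.members],
                         provenance=[f"core(greedy:{core.id})"])
            cl.hmm = rebuild(msa)
            clusters.append(cl)
            next_id += 1
        else:
            for seq, _ in core.members:  # core too diverse: dissolve
                pool.add(seq)

    for r in range(config.n_rounds):
        ext_thr = config.extension_thresholds[r]
        merge_thr = config.merge_thresholds[r]
        clusters, pool, distant = extension_round(
            clusters, pool, ext_thr, config, background)
        n_after_ext = len(clusters)
        if clusters:
            if r < config.n_rounds - 1:
                clusters = _merge.heuristic_merge(
                    clusters, distant, merge_thr, rebuild,
                    diversity_ok=lambda m: diversity_ok(m, config))
            else:
                clusters = _merge.hierarchical_merge(
                    clusters, merge_thr, rebuild,
                    diversity_ok=lambda m: diversity_ok(m, config))
        log.append({
            "stage": f"round {r + 1}",
            "extension_threshold": ext_thr,
            "merge_threshold": merge_thr,
            "n_clusters_after_extension": n_after_ext,
            "n_clusters_after_merge": len(clusters),
            "n_assigned": sum(c.size_unique for c in clusters),
            "pool_size": len(pool),
        })

    result = RunResult(
        clusters=sorted(clusters, key=lambda c: c.id),
        unassigned=sorted(pool, key=lambda u: u.sequence),
        log=log,
    )
    result.validate(data)
    return result
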
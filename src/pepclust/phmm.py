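"""Profile hidden Markov models built from cluster MSAs, and local
Viterbi search of the sequence pool.

The model is the standard match/insert/delete architecture with local
(fragment) alignment semantics: entry is uniform over match states,
exit is free from any match state, and flanking unaligned residues are
neither rewarded nor penalized.  Scores are log2-odds (bits) against an
i.i.d. background null; insert states emit the background and so score
zero per inserted residue apart from their transition costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import MSA
from .substitution import AA_INDEX, blosum62_background

NEG_INF = float("-inf")


@dataclass
class ProfileHMM:
    """A profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions[k]`` is the emission distribution of match state
    ``k``; transition arrays are indexed by the source state, e.g.
    ``t_mm[k]`` is P(M_k -> M_{k+1}) for ``k < n_match - 1``.  Delete
    states D_k exist for ``k >= 1`` (entry is into match states only).
    """

    n_match: int
    match_emissions: np.ndarray = field(repr=False)   # (n, 20)
    insert_emissions: np.ndarray = field(repr=False)  # (20,)
    t_mm: np.ndarray = field(repr=False)  # (n-1,) M_k -> M_{k+1}
    t_mi: np.ndarray = field(repr=False)  # (n-1,) M_k -> I_k
    t_md: np.ndarray = field(repr=False)  # (n-1,) M_k -> D_{k+1}
    t_im: np.ndarray = field(repr=False)  # (n-1,) I_k -> M_{k+1}
    t_ii: np.ndarray = field(repr=False)  # (n-1,) I_k -> I_k
    t_dm: np.ndarray = field(repr=False)  # (n-1,) D_{k+1} <- ... P(D_k -> M_{k+1}) at [k-1]? see note
    t_dd: np.ndarray = field(repr=False)  # (n-1,)
    match_column_map: list[int] = field(default_factory=list)
    background: np.ndarray = field(default_factory=blosum62_background, repr=False)

    # Note on delete indexing: t_dm[k] = P(D_{k+1} -> M_{k+2}) would be
    # awkward; instead both delete arrays are indexed by the *target*
    # transition slot: t_dm[k] = P(D_k -> M_{k+1}) and
    # t_dd[k] = P(D_k -> D_{k+1}) for k in 1..n-2, with index 0 unused
    # (D_0 does not exist).  Arrays have length max(n-1, 1).

    def __post_init__(self) -> None:
        if self.n_match < 1:
            raise ValueError("model needs at least one match state")
        if list(self.match_column_map) != sorted(set(self.match_column_map)):
            raise ValueError("match_column_map must be strictly increasing")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1 per state")

    # -- derived log-space parameters (cached) ------------------------------

    @property
    def match_log_odds(self) -> np.ndarray:
        """(n, 20) array of log2(e_k(r) / bg(r))."""
        if not hasattr(self, "_mlo"):
            self._mlo = np.log2(self.match_emissions / self.background[None, :])
        return self._mlo

    def _log_t(self) -> dict[str, np.ndarray]:
        if not hasattr(self, "_lt"):
            with np.errstate(divide="ignore"):
                self._lt = {name: np.log2(getattr(self, "t_" + name))
                            for name in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
        return self._lt

    @property
    def entry_log(self) -> float:
        return float(np.log2(1.0 / self.n_match))


@dataclass(frozen=True)
class ScoredHit:
    """One sequence scored against one profile HMM."""

    sequence: str
    bit_score: float
    path: tuple = ()       # ((op, match_state, seq_pos), ...) op in {M, I, D}
    span: tuple[int, int] = (0, 0)  # half-open residue interval aligned


def build_phmm(
    msa: MSA,
    match_cols: list[int],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    min_match: int = 4,
) -> ProfileHMM:
    """Estimate a profile HMM from the match columns of a cluster MSA.

    Match emissions are observed non-gap residue counts plus
    background-proportional pseudocounts (total weight
    *pseudocount_weight* per column), normalized.  Transitions are
    tallied from each row's implied path through match/insert/delete
    states, with a pseudocount of 1 per transition type, normalized per
    source state.  Insert states emit the background.
    """
    if background is None:
        background = blosum62_background()
    n = len(match_cols)
    if n < min_match:
        raise ValueError(
            f"{n} match columns < required minimum {min_match}")

    # emissions
    em = np.zeros((n, 20))
    for k, col in enumerate(match_cols):
        counts = np.zeros(20)
        for ch in msa.column(col):
            if ch != "-":
                counts[AA_INDEX[ch]] += 1
        counts += pseudocount_weight * background
        em[k] = counts / counts.sum()

    # transition tallies from row paths
    nt = max(n - 1, 1)
    c_mm = np.zeros(nt); c_mi = np.zeros(nt); c_md = np.zeros(nt)
    c_im = np.zeros(nt); c_ii = np.zeros(nt)
    c_dm = np.zeros(nt); c_dd = np.zeros(nt)
    match_set = {col: k for k, col in enumerate(match_cols)}

    for _, aligned in msa.rows:
        events = _row_events(aligned, match_cols, match_set)
        for (op1, k1), (op2, k2) in zip(events, events[1:]):
            if op1 == "M" and op2 == "M":
                c_mm[k1] += 1
            elif op1 == "M" and op2 == "I":
                c_mi[k1] += 1
            elif op1 == "M" and op2 == "D":
                c_md[k1] += 1
            elif op1 == "I" and op2 == "M":
                c_im[k1] += 1
            elif op1 == "I" and op2 == "I":
                c_ii[k1] += 1
            elif op1 == "D" and op2 == "M":
                c_dm[k1] += 1
            elif op1 == "D" and op2 == "D":
                c_dd[k1] += 1
            # I<->D adjacencies have no edge in this architecture; skipped

    def norm2(a, b):
        ta, tb = a + 1.0, b + 1.0
        s = ta + tb
        return ta / s, tb / s

    mm, mi, md = c_mm + 1.0, c_mi + 1.0, c_md + 1.0
    s = mm + mi + md
    t_mm, t_mi, t_md = mm / s, mi / s, md / s
    t_im, t_ii = norm2(c_im, c_ii)
    t_dm, t_dd = norm2(c_dm, c_dd)

    return ProfileHMM(
        n_match=n,
        match_emissions=em,
        insert_emissions=background.copy(),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        match_column_map=list(match_cols),
        background=background,
    )


def _row_events(aligned: str, match_cols: list[int],
                match_set: dict[int, int]) -> list[tuple[str, int]]:
    """The (state, index) event sequence a row implies, fragment-style.

    Leading/trailing delete runs are trimmed (rows are local fragments);
    residues in non-match columns outside the first/last match-state
    event are flanks and carry no transition information.
    """
    events: list[tuple[str, int]] = []
    k_passed = -1  # index of last match state at or before current column
    for col, ch in enumerate(aligned):
        if col in match_set:
            k_passed = match_set[col]
            events.append(("M" if ch != "-" else "D", k_passed))
        elif ch != "-" and 0 <= k_passed < len(match_cols) - 1:
            events.append(("I", k_passed))
    # trim leading/trailing D (and orphan I before any M / after last M)
    first = next((i for i, (op, _) in enumerate(events) if op == "M"), None)
    if first is None:
        return []
    last = max(i for i, (op, _) in enumerate(events) if op == "M")
    return events[first:last + 1]


# ---------------------------------------------------------------------------
# local Viterbi
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def viterbi_local(hmm: ProfileHMM, seq: str) -> ScoredHit:
    """Best local alignment of *seq* to the model, with traceback.

    Returns the maximum-log-odds path: free entry into any match state
    (uniform entry probability), free exit from any match state,
    unaligned flanks scoring zero.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    n, L = hmm.n_match, len(seq)
    x = _encode(seq)
    mlo = hmm.match_log_odds
    lt = hmm._log_t()
    entry = hmm.entry_log

    # V*[c, k]: best score of a path ending in state * at match slot k
    # having consumed c residues.  Pointers record the predecessor.
    VM = np.full((L + 1, n), NEG_INF)
    VI = np.full((L + 1, n), NEG_INF)
    VD = np.full((L + 1, n), NEG_INF)
    PM = np.zeros((L + 1, n), dtype=np.int8)  # 0=begin 1=MM 2=IM 3=DM
    PI = np.zeros((L + 1, n), dtype=np.int8)  # 1=MI 2=II
    PD = np.zeros((L + 1, n), dtype=np.int8)  # 1=MD 2=DD

    for c in range(1, L + 1):
        e = mlo[:, x[c - 1]]
        for k in range(n):
            opts = [entry]
            if k > 0:
                opts += [VM[c - 1, k - 1] + lt["mm"][k - 1],
                         VI[c - 1, k - 1] + lt["im"][k - 1],
                         VD[c - 1, k - 1] + lt["dm"][k - 1]]
            best = int(np.argmax(opts))
            VM[c, k] = e[k] + opts[best]
            PM[c, k] = best
        for k in range(n - 1):
            o1 = VM[c - 1, k] + lt["mi"][k]
            o2 = VI[c - 1, k] + lt["ii"][k]
            VI[c, k] = max(o1, o2)
            PI[c, k] = 1 if o1 >= o2 else 2
        for k in range(1, n):
            o1 = VM[c, k - 1] + lt["md"][k - 1]
            o2 = VD[c, k - 1] + lt["dd"][k - 1] if k > 1 else NEG_INF
            VD[c, k] = max(o1, o2)
            PD[c, k] = 1 if o1 >= o2 else 2

    # exit from any match state; deterministic tie-break: smallest c, then k
    flatVM = VM[1:, :]
    best_flat = int(flatVM.argmax())
    c_end, k_end = best_flat // n + 1, best_flat % n
    bit_score = float(VM[c_end, k_end])

    # traceback
    ops: list[tuple[str, int, int | None]] = []
    state, c, k = "M", c_end, k_end
    while True:
        if state == "M":
            ops.append(("M", k, c - 1))
            ptr = PM[c, k]
            if ptr == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(ptr)]
            if state != "D":
                c -= 1
            else:
                c -= 1
            k -= 1
        elif state == "I":
            ops.append(("I", k, c - 1))
            ptr = PI[c, k]
            state = "M" if ptr == 1 else "I"
            c -= 1
        else:  # D
            ops.append(("D", k, None))
            ptr = PD[c, k]
            state = "M" if ptr == 1 else "D"
            k -= 1
    ops.reverse()
    start = next(i for op, _, i in ops if op == "M")
    end = max(i for op, _, i in ops if i is not None) + 1
    return ScoredHit(sequence=seq, bit_score=bit_score,
                     path=tuple(ops), span=(start, end))


def score_sequences(hmm: ProfileHMM, seqs: list[str]) -> np.ndarray:
    """Vectorized local-Viterbi bit scores for many sequences (no paths).

    Sequences are grouped by length internally; returns scores in input
    order.
    """
    out = np.empty(len(seqs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in by_len.items():
        X = np.stack([_encode(seqs[i]) for i in idxs])  # (B, L)
        out[idxs] = _batch_scores(hmm, X)
    return out


def _batch_scores(hmm: ProfileHMM, X: np.ndarray) -> np.ndarray:
    n = hmm.n_match
    B, L = X.shape
    mlo = hmm.match_log_odds  # (n, 20)
    lt = hmm._log_t()
    entry = hmm.entry_log

    VM = np.full((B, n), NEG_INF)
    VI = np.full((B, n), NEG_INF)
    VD = np.full((B, n), NEG_INF)
    best = np.full(B, NEG_INF)
    shift_pad = np.full((B, 1), NEG_INF)

    for c in range(L):
        e = mlo[:, X[:, c]].T  # (B, n)
        prevM = np.hstack([shift_pad, VM[:, :-1]])
        prevI = np.hstack([shift_pad, VI[:, :-1]])
        prevD = np.hstack([shift_pad, VD[:, :-1]])
        cand = np.maximum(
            np.maximum(prevM + np.concatenate([[0.0], lt["mm"]])[None, :n],
                       prevI + np.concatenate([[0.0], lt["im"]])[None, :n]),
            np.maximum(prevD + np.concatenate([[0.0], lt["dm"]])[None, :n],
                       np.full((B, n), entry)))
        newVM = e + cand
        if n > 1:
            newVI = np.full((B, n), NEG_INF)
            newVI[:, :n - 1] = np.maximum(VM[:, :n - 1] + lt["mi"][None, :],
                                          VI[:, :n - 1] + lt["ii"][None, :])
        else:
            newVI = VI
        newVD = np.full((B, n), NEG_INF)
        for k in range(1, n):
            o1 = newVM[:, k - 1] + lt["md"][k - 1]
            o2 = newVD[:, k - 1] + lt["dd"][k - 1] if k > 1 else np.full(B, NEG_INF)
            newVD[:, k] = np.maximum(o1, o2)
        VM, VI, VD = newVM, newVI, newVD
        best = np.maximum(best, VM.max(axis=1))
    return best


def search_pool(hmm: ProfileHMM, pool, threshold: float,
                with_paths: bool = True) -> list[ScoredHit]:
    """All pool sequences scoring at least *threshold* bits, sorted by
    bit score descending (ties alphabetic).  The pool is not modified."""
    seqs = sorted(s.sequence for s in pool)
    if not seqs:
        return []
    scores = score_sequences(hmm, seqs)
    hits = []
    for s, sc in zip(seqs, scores):
        if sc >= threshold:
            hits.append(viterbi_local(hmm, s) if with_paths
                        else ScoredHit(sequence=s, bit_score=float(sc)))
    hits.sort(key=lambda h: (-h.bit_score, h.sequence))
    return hits


def distant_hits(hmm: ProfileHMM, pool, distant_threshold: float) -> set[str]:
    """Pool sequence ids scoring at least the (lower) distant threshold;
    a superset of the extension hit set."""
    seqs = sorted(s.sequence for s in pool)
    if not seqs:
        return set()
    scores = score_sequences(hmm, seqs)
    return {s for s, sc in zip(seqs, scores) if sc >= distant_threshold}
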
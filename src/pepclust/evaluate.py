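"""Clustering-quality metrics and per-label summaries.

The headline quality score is the Kullback–Leibler divergence of MSA
column residue frequencies from the background, summed over a chosen
column set — either the match columns only or every column.  Per-label
copy-count matrices summarize how clusters distribute over experiment
categories (e.g. selection/amplification rounds per target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import MSA, match_columns
from .pipeline import RunResult
from .substitution import blosum62_background


def kld(msa: MSA, columns: list[int],
        background: np.ndarray | None = None) -> float:
    """KL divergence (bits) of the given columns from the background.

    ``sum_cols sum_r f(r) log2(f(r)/bg(r))`` with ``f`` the non-gap
    residue frequencies; zero-frequency terms contribute 0.  No
    pseudocounts, so single-residue columns are fine (finite).
    """
    if not columns:
        raise ValueError("column set must be non-empty")
    if background is None:
        background = blosum62_background()
    total = 0.0
    for c in columns:
        f = msa.residue_frequencies(c)
        nz = f > 0
        total += float((f[nz] * np.log2(f[nz] / background[nz])).sum())
    return total


def dataset_kld(result: RunResult, over: str = "match",
                background: np.ndarray | None = None,
                gap_threshold: float = 0.05, ic_threshold: float = 1.2,
                weighted: bool = True) -> float:
    """Dataset-level KLD: per-cluster KLD combined over clusters.

    ``over`` selects the column set per cluster ("match" or "all").
    With *weighted* (default) clusters are weighted by their number of
    unique sequences; otherwise a plain mean is taken.
    """
    values, weights = [], []
    for c in result.clusters:
        if over == "match":
            cols = match_columns(c.msa, gap_threshold, ic_threshold)
        elif over == "all":
            cols = list(range(c.msa.width))
        else:
            raise ValueError(f"unknown column set {over!r}")
        if not cols:
            continue
        values.append(kld(c.msa, cols, background))
        weights.append(c.size_unique)
    if not values:
        return 0.0
    if weighted:
        return float(np.average(values, weights=weights))
    return float(np.mean(values))


@dataclass(frozen=True)
class DatasetSummary:
    """Headline counts of a clustering run, with derived percentages."""

    n_unique_total: int
    n_unique_clustered: int
    copy_total: int
    copy_clustered: int
    n_clusters: int
    cluster_sizes: tuple[int, ...]

    @property
    def percent_unique_clustered(self) -> float:
        return round(100.0 * self.n_unique_clustered / self.n_unique_total, 1)

    @property
    def percent_copies_clustered(self) -> float:
        return round(100.0 * self.copy_clustered / self.copy_total, 1)


def summary_from_counts(n_unique_clustered: int, n_unique_total: int,
                        copy_clustered: int, copy_total: int,
                        n_clusters: int = 0,
                        cluster_sizes: tuple[int, ...] = ()) -> DatasetSummary:
    """Build a summary directly from printed counts (no run needed)."""
    return DatasetSummary(
        n_unique_total=n_unique_total,
        n_unique_clustered=n_unique_clustered,
        copy_total=copy_total,
        copy_clustered=copy_clustered,
        n_clusters=n_clusters,
        cluster_sizes=cluster_sizes,
    )


def dataset_summary(result: RunResult) -> DatasetSummary:
    """Summarize a pipeline run: how much of the dataset was clustered."""
    n_uc = sum(c.size_unique for c in result.clusters)
    c_c = sum(c.size_total for c in result.clusters)
    n_ut = n_uc + len(result.unassigned)
    c_t = c_c + sum(u.total_count for u in result.unassigned)
    return DatasetSummary(
        n_unique_total=n_ut, n_unique_clustered=n_uc,
        copy_total=c_t, copy_clustered=c_c,
        n_clusters=len(result.clusters),
        cluster_sizes=tuple(c.size_unique for c in result.clusters),
    )


def label_matrix(result: RunResult, normalize: bool = False) -> pd.DataFrame:
    """Cluster x label copy-count matrix.

    With *normalize* each label column is divided by that label's
    dataset-wide copy total (clustered + unassigned), so column sums
    over clusters are at most 1.
    """
    labels = sorted({l for c in result.clusters for m in c.members
                     for l in m.counts})
    if not labels:
        raise ValueError(
            "no labels present in clustered data; use dataset_summary for "
            "unlabeled datasets")
    ids = [c.id for c in sorted(result.clusters, key=lambda c: c.id)]
    mat = pd.DataFrame(0, index=pd.Index(ids, name="cluster_id"),
                       columns=labels, dtype=float)
    for c in result.clusters:
        for m in c.members:
            for l, n in m.counts.items():
                mat.loc[c.id, l] += n
    if normalize:
        totals = {l: 0.0 for l in labels}
        for group in (m for c in result.clusters for m in c.members):
            for l, n in group.counts.items():
                if l in totals:
                    totals[l] += n
        for u in result.unassigned:
            for l, n in u.counts.items():
                if l in totals:
                    totals[l] += n
        for l in labels:
            mat[l] /= totals[l]
    return mat


def profile_correlation(m: pd.DataFrame, a: int, b: int) -> float:
    """Row distance ``1 - cor(v_a, v_b)`` (Pearson), in [0, 2]."""
    va, vb = m.loc[a].to_numpy(float), m.loc[b].to_numpy(float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("correlation undefined for zero-variance profile")
    return float(1.0 - np.corrcoef(va, vb)[0, 1])


def cluster_purity(result: RunResult, truth: dict[str, str]) -> dict[int, float]:
    """Per-cluster fraction of members matching the majority planted motif.

    ``truth`` maps each sequence to a motif name or ``"noise"``.  A
    cluster whose majority assignment is noise has purity 0 (noise is
    never a motif); noise members always count against purity.
    """
    out: dict[int, float] = {}
    for c in result.clusters:
        assignments = [truth[m.sequence] for m in c.members]
        counts: dict[str, int] = {}
        for a in assignments:
            counts[a] = counts.get(a, 0) + 1
        majority = max(sorted(counts), key=lambda k: counts[k])
        if majority == "noise":
            out[c.id] = 0.0
        else:
            out[c.id] = counts[majority] / len(assignments)
    return out
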
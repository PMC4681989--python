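"""Reading peptide datasets, deduplication, and result export.

Three input dialects are supported:

* **fasta** — one peptide per record; headers may carry ``id|count|label``
  fields (missing fields default to count 1, no label).
* **tabular** — TSV with columns ``sequence``, ``count``, ``label``
  (header row optional; count and label columns optional).
* **plain** — one sequence per line, no counts or labels.

Occurrences are deduplicated into :class:`UniqueSequence` records that
keep per-label copy counts, mirroring how display-library reads are
collapsed before clustering while preserving copy-number information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .substitution import AMINO_ACIDS

#: Label under which unlabeled occurrences are accumulated.
DEFAULT_LABEL = "_nolabel"

_VALID = set(AMINO_ACIDS)


class ParseError(ValueError):
    """Malformed input record; message names the offending line."""


@dataclass(frozen=True)
class Occurrence:
    """One (possibly multi-copy) observation of a peptide sequence."""

    sequence: str
    label: str | None = None
    count: int = 1


@dataclass
class UniqueSequence:
    """A deduplicated peptide with per-label copy counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def _check_sequence(seq: str, where: str, on_invalid: str) -> str | None:
    """Validate/uppercase a peptide; returns None if the record is skipped."""
    seq = seq.strip().upper()
    if not seq:
        raise ParseError(f"empty sequence at {where}")
    bad = set(seq) - _VALID
    if bad:
        msg = (f"non-canonical residue(s) {''.join(sorted(bad))!r} "
               f"in {seq!r} at {where}")
        if on_invalid == "error":
            raise ParseError(msg)
        warnings.warn(msg + "; record skipped", stacklevel=3)
        return None
    return seq


def read_sequences(path, fmt: str, on_invalid: str = "skip") -> list[Occurrence]:
    """Read peptide occurrences from *path* in the named dialect.

    Parameters
    ----------
    path : path-like
        Input file.
    fmt : {"fasta", "tabular", "plain"}
        Input dialect.
    on_invalid : {"skip", "error"}
        Policy for records containing non-canonical residues
        (B, J, O, U, X, Z, ``*``): skip with a warning (default) or
        raise a :class:`ParseError`.
    """
    path = Path(path)
    if fmt not in ("fasta", "tabular", "plain"):
        raise ValueError(f"unknown format {fmt!r}")
    if on_invalid not in ("skip", "error"):
        raise ValueError(f"unknown on_invalid policy {on_invalid!r}")

    occurrences: list[Occurrence] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            where = f"{path.name}, record {rec.id!r}"
            seq = _check_sequence(str(rec.seq), where, on_invalid)
            if seq is None:
                continue
            fields = rec.description.split()[0].split("|")
            count, label = 1, None
            if len(fields) >= 2 and fields[1]:
                try:
                    count = int(fields[1])
                except ValueError as exc:
                    raise ParseError(f"bad count field at {where}") from exc
                if count < 1:
                    raise ParseError(f"non-positive count at {where}")
            if len(fields) >= 3 and fields[2]:
                label = fields[2]
            occurrences.append(Occurrence(seq, label, count))
    elif fmt == "tabular":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].strip().lower() == "sequence":
                    continue  # optional header row
                where = f"{path.name}:{lineno}"
                seq = _check_sequence(parts[0], where, on_invalid)
                if seq is None:
                    continue
                count, label = 1, None
                if len(parts) >= 2 and parts[1].strip():
                    try:
                        count = int(parts[1])
                    except ValueError as exc:
                        raise ParseError(f"bad count at {where}") from exc
                    if count < 1:
                        raise ParseError(f"non-positive count at {where}")
                if len(parts) >= 3 and parts[2].strip():
                    label = parts[2].strip()
                occurrences.append(Occurrence(seq, label, count))
    else:  # plain
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                seq = _check_sequence(line, f"{path.name}:{lineno}", on_invalid)
                if seq is not None:
                    occurrences.append(Occurrence(seq))

    if not occurrences:
        raise ParseError(f"no sequences read from {path}")
    return occurrences


def deduplicate(occurrences: list[Occurrence]) -> list[UniqueSequence]:
    """Collapse occurrences into unique sequences with per-label counts.

    Order-insensitive up to output order (first-seen); unlabeled
    occurrences accumulate under :data:`DEFAULT_LABEL`.
    """
    by_seq: dict[str, UniqueSequence] = {}
    for occ in occurrences:
        u = by_seq.get(occ.sequence)
        if u is None:
            u = by_seq[occ.sequence] = UniqueSequence(occ.sequence)
        label = occ.label if occ.label is not None else DEFAULT_LABEL
        u.counts[label] = u.counts.get(label, 0) + occ.count
    return list(by_seq.values())


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def write_afa(rows: list[tuple[str, str]], path) -> None:
    """Write an aligned FASTA (``-`` gaps)."""
    with open(path, "w") as fh:
        for name, aligned in rows:
            fh.write(f">{name}\n{aligned}\n")


def read_afa(path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def export_results(result, out_dir) -> dict[str, Path]:
    """Write the full result surface for a pipeline run.

    Produces ``clusters.tsv`` (one row per cluster), one aligned FASTA
    ``cluster_<id>.afa`` per cluster, ``unassigned.tsv`` and
    ``label_matrix.tsv``.  Unassigned rows and MSA headers round-trip
    through :func:`read_sequences`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    labels = sorted({l for c in result.clusters for m in c.members for l in m.counts}
                    | {l for u in result.unassigned for l in u.counts})

    rows = []
    for c in sorted(result.clusters, key=lambda c: c.id):
        per_label = {l: sum(m.counts.get(l, 0) for m in c.members) for l in labels}
        rows.append({
            "cluster_id": c.id,
            "size_unique": len(c.members),
            "size_total": sum(m.total_count for m in c.members),
            **{f"count_{l}": per_label[l] for l in labels},
            "consensus": c.msa.consensus(),
            "n_match_states": c.hmm.n_match if c.hmm is not None else 0,
        })
        afa = out_dir / f"cluster_{c.id}.afa"
        member_count = {m.sequence: m.total_count for m in c.members}
        member_label = {}
        for m in c.members:
            nondefault = [l for l in m.counts if l != DEFAULT_LABEL]
            member_label[m.sequence] = nondefault[0] if len(nondefault) == 1 and DEFAULT_LABEL not in m.counts else ""
        write_afa(
            [(f"{rid}|{member_count[rid]}|{member_label[rid]}".rstrip("|"), aligned)
             for rid, aligned in c.msa.rows],
            afa,
        )
        written[afa.name] = afa

    import pandas as pd

    summary = out_dir / "clusters.tsv"
    cols = ["cluster_id", "size_unique", "size_total",
            *[f"count_{l}" for l in labels], "consensus", "n_match_states"]
    pd.DataFrame(rows, columns=cols).to_csv(summary, sep="\t", index=False)
    written[summary.name] = summary

    unassigned = out_dir / "unassigned.tsv"
    with open(unassigned, "w") as fh:
        fh.write("sequence\tcount\tlabel\n")
        for u in sorted(result.unassigned, key=lambda u: u.sequence):
            for label, n in sorted(u.counts.items()):
                shown = "" if label == DEFAULT_LABEL else label
                fh.write(f"{u.sequence}\t{n}\t{shown}\n")
    written[unassigned.name] = unassigned

    matrix = out_dir / "label_matrix.tsv"
    import pandas as pd  # noqa: F811

    mat = pd.DataFrame(
        [[sum(m.counts.get(l, 0) for m in c.members) for l in labels]
         for c in sorted(result.clusters, key=lambda c: c.id)],
        index=[c.id for c in sorted(result.clusters, key=lambda c: c.id)],
        columns=labels,
    )
    mat.index.name = "cluster_id"
    mat.to_csv(matrix, sep="\t")
    written[matrix.name] = matrix
    return written
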
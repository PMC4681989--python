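"""The cluster container shared by extension, merging and reporting."""

from __future__ import annotations

from dataclasses import dataclass, field

from .msa import MSA
from .seqio import UniqueSequence


@dataclass
class Cluster:
    """A cluster: members, their MSA, and the profile HMM built from it.

    The HMM is rebuilt after every mutation (extension batch or merge);
    ``provenance`` records those events for the run log.
    """

    id: int
    msa: MSA
    members: list[UniqueSequence]
    hmm: object | None = None  # ProfileHMM, rebuilt by the pipeline
    provenance: list[str] = field(default_factory=list)

    @property
    def size_unique(self) -> int:
        return len(self.members)

    @property
    def size_total(self) -> int:
        return sum(m.total_count for m in self.members)

    def validate(self) -> None:
        self.msa.validate()
        row_ids = sorted(rid for rid, _ in self.msa.rows)
        member_ids = sorted(m.sequence for m in self.members)
        if row_ids != member_ids:
            raise AssertionError(
                f"cluster {self.id}: members and MSA rows disagree")
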
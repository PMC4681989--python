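"""Amino-acid substitution matrices and background frequencies.

Scoring of short peptides during greedy seeding uses an integer
substitution matrix (BLOSUM62 by default).  The same background residue
distribution (BLOSUM62 marginals) is shared by the profile-HMM null
model and the synthetic-data generator so that log-odds scores are
internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 canonical residues, in the fixed internal order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# BLOSUM62 marginal (background) residue frequencies, the standard
# values used by log-odds null models; indexed like AMINO_ACIDS.
_BLOSUM62_MARGINALS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


def blosum62_background() -> np.ndarray:
    """Background residue frequencies (BLOSUM62 marginals), normalized."""
    v = np.array([_BLOSUM62_MARGINALS[a] for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


def uniform_background() -> np.ndarray:
    """Uniform background over the 20 canonical residues."""
    return np.full(20, 1.0 / 20.0)


@dataclass
class SubstitutionMatrix:
    """Symmetric integer residue-pair scores over the 20-letter alphabet.

    Attributes
    ----------
    name : str
        Matrix identifier (e.g. ``"BLOSUM62"``).
    scores : numpy.ndarray
        ``(20, 20)`` integer array indexed by :data:`AA_INDEX`.
    """

    name: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.array_equal(s, s.T):
            raise ValueError(f"matrix {self.name!r} is not symmetric")
        self.scores = s
        # BLOSUM-family sanity: a residue should never prefer a substitution
        # over itself.  Violations are tolerated (custom matrices) but noted.
        diag = np.diag(s)
        if (s > diag[:, None]).any():
            import warnings

            warnings.warn(
                f"matrix {self.name!r}: some off-diagonal scores exceed "
                "the diagonal; greedy self-alignment may not dominate",
                stacklevel=2,
            )

    def score(self, a: str, b: str) -> int:
        return int(self.scores[AA_INDEX[a], AA_INDEX[b]])

    @classmethod
    def from_biopython(cls, name: str) -> "SubstitutionMatrix":
        """Load a named matrix (``BLOSUM62``, ``PAM250``, ...) from biopython."""
        arr = substitution_matrices.load(name)
        m = np.zeros((20, 20), dtype=int)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = int(arr[a, b])
        return cls(name=name, scores=m)

    @classmethod
    def from_file(cls, path) -> "SubstitutionMatrix":
        """Read a square NCBI/EMBOSS-format matrix text file."""
        arr = substitution_matrices.read(str(path))
        missing = [a for a in AMINO_ACIDS if a not in arr.alphabet]
        if missing:
            raise ValueError(f"matrix file lacks residues: {''.join(missing)}")
        m = np.zeros((20, 20), dtype=int)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = int(arr[a, b])
        import os

        return cls(name=os.path.basename(str(path)), scores=m)


def blosum62() -> SubstitutionMatrix:
    """The default greedy-clustering matrix."""
    return SubstitutionMatrix.from_biopython("BLOSUM62")
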
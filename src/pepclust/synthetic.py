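"""Planted-motif synthetic peptide datasets with ground truth.

Emulates the structure of display-library screens: each sequence either
carries one of a set of planted short linear motifs at a random offset
inside background flanks, or is pure background noise.  Copy numbers
follow a truncated discrete power law (a few very popular clones, a
long tail of rare ones) and occurrences can be spread over experiment
labels with fixed mixing weights.  Everything is determined by the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Occurrence
from .substitution import AMINO_ACIDS, blosum62_background


@dataclass(frozen=True)
class MotifSpec:
    """One planted motif.

    ``pattern`` is a list of position specs: either ``None`` for a
    background ("any") position or a mapping residue -> weight summing
    to 1.  Example: the class I polyproline ligand ``[R/K]xxPxxP`` is
    ``[{R: .5, K: .5}, None, None, {P: 1}, None, None, {P: 1}]``.
    """

    name: str
    pattern: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError("pattern must have at least 4 positions")
        for spec in self.pattern:
            if spec is not None and abs(sum(spec.values()) - 1.0) > 1e-9:
                raise ValueError("position weights must sum to 1")

    @classmethod
    def from_string(cls, name: str, pattern: str) -> "MotifSpec":
        """Parse a pattern like ``"[RK]xxPxxP"`` (x = any, equal weights
        inside brackets)."""
        specs: list = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.index("]", i)
                residues = pattern[i + 1:j]
                specs.append({r: 1.0 / len(residues) for r in residues})
                i = j + 1
            elif ch in ("x", "X"):
                specs.append(None)
                i += 1
            else:
                specs.append({ch: 1.0})
                i += 1
        return cls(name=name, pattern=tuple(specs))


class GroundTruth(dict):
    """Mapping sequence -> motif name or ``"noise"``."""


def _power_law_copies(rng: np.random.Generator, n: int,
                      alpha: float, k_max: int) -> np.ndarray:
    k = np.arange(1, k_max + 1, dtype=float)
    p = k ** (-alpha)
    p /= p.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n, p=p)


def _sample_background(rng: np.random.Generator, n: int,
                       background: np.ndarray) -> str:
    idx = rng.choice(20, size=n, p=background)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _sample_motif_sequence(rng: np.random.Generator, motif: MotifSpec,
                           length: int, background: np.ndarray,
                           fixed_offset: int | None) -> str:
    m = len(motif.pattern)
    if m > length:
        raise ValueError(f"pattern {motif.name!r} longer than peptide length")
    offset = (fixed_offset if fixed_offset is not None
              else int(rng.integers(0, length - m + 1)))
    core = []
    for spec in motif.pattern:
        if spec is None:
            core.append(_sample_background(rng, 1, background))
        else:
            residues = sorted(spec)
            weights = np.array([spec[r] for r in residues])
            core.append(residues[int(rng.choice(len(residues), p=weights))])
    left = _sample_background(rng, offset, background)
    right = _sample_background(rng, length - m - offset, background)
    return left + "".join(core) + right


def generate_dataset(
    motifs: list[MotifSpec],
    n_per_motif: list[int],
    n_noise: int,
    length: int = 12,
    labels: list[tuple[str, float]] | None = None,
    copy_alpha: float = 2.0,
    copy_max: int = 10_000,
    seed: int = 0,
    background: np.ndarray | None = None,
    fixed_offset: int | None = None,
) -> tuple[list[Occurrence], GroundTruth]:
    """Generate a planted-motif dataset plus its ground truth.

    Unique sequences are sampled (collisions re-drawn) per motif and
    for noise; each receives a power-law copy number
    ``P(k) ~ k**-copy_alpha`` truncated at *copy_max*, split over
    *labels* by their mixing weights when given.
    """
    if len(motifs) != len(n_per_motif):
        raise ValueError("motifs and n_per_motif must have equal length")
    if background is None:
        background = blosum62_background()
    rng = np.random.default_rng(seed)

    truth = GroundTruth()
    sequences: list[tuple[str, str]] = []  # (sequence, truth name)
    for motif, n in zip(motifs, n_per_motif):
        for _ in range(n):
            while True:
                s = _sample_motif_sequence(rng, motif, length, background,
                                           fixed_offset)
                if s not in truth:
                    break
            truth[s] = motif.name
            sequences.append((s, motif.name))
    for _ in range(n_noise):
        while True:
            s = _sample_background(rng, length, background)
            if s not in truth:
                break
        truth[s] = "noise"
        sequences.append((s, "noise"))

    copies = _power_law_copies(rng, len(sequences), copy_alpha, copy_max)
    occurrences: list[Occurrence] = []
    for (seq, _), total in zip(sequences, copies):
        total = int(total)
        if labels:
            names = [l for l, _ in labels]
            weights = np.array([w for _, w in labels], dtype=float)
            weights /= weights.sum()
            split = rng.multinomial(total, weights)
            for name, n in zip(names, split):
                if n > 0:
                    occurrences.append(Occurrence(seq, name, int(n)))
        else:
            occurrences.append(Occurrence(seq, None, total))
    return occurrences, truth


#: Canonical class I / class II polyproline SH3 ligand motifs.
CLASS_I = MotifSpec.from_string("class_I", "[RK]xxPxxP")
CLASS_II = MotifSpec.from_string("class_II", "PxxPx[RK]")


def sh3_like_fixture(seed: int = 42) -> tuple[list[Occurrence], GroundTruth]:
    """A structural mimic of a two-specificity SH3 screen.

    2457 unique 12-mers: 1738 carrying the class I motif
    ``[R/K]xxPxxP``, 415 carrying the class II motif ``PxxPx[R/K]``
    and 304 background-noise sequences (~12 % noise), power-law copy
    numbers, no labels.
    """
    return generate_dataset(
        motifs=[CLASS_I, CLASS_II],
        n_per_motif=[1738, 415],
        n_noise=304,
        length=12,
        seed=seed,
    )


def write_dataset(occurrences: list[Occurrence], truth: GroundTruth,
                  data_path, truth_path) -> None:
    """Write the tabular input dialect plus a ``truth.tsv`` sidecar."""
    with open(data_path, "w") as fh:
        fh.write("sequence\tcount\tlabel\n")
        for occ in occurrences:
            fh.write(f"{occ.sequence}\t{occ.count}\t{occ.label or ''}\n")
    with open(truth_path, "w") as fh:
        fh.write("sequence\tmotif\n")
        for seq in sorted(truth):
            fh.write(f"{seq}\t{truth[seq]}\n")
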
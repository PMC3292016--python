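"""Synthetic labeled datasets for dependency-free end-to-end testing.

Real antifreeze-protein benchmarks require downloading curated sequence
sets and running PSI-BLAST against a large database. This module instead
generates labeled sequences from an i.i.d. residue model: positives are
drawn from one composition bias vector, negatives from another, with
lengths uniform in a range. The distance between the two bias vectors is
the dial for class separability — identical vectors give a no-signal
dataset (CV accuracy ~50%), disjoint-support vectors a perfectly
separable one. Mock PSSM profiles (see :func:`afpkit.pssm
.generate_mock_pssm`) can be attached per sequence with derived seeds.

The default mirrors a balanced two-class training design at n = 100 per
class with lengths 50-150, long enough for PseAAC at lambda = 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from afpkit.pssm import PSSMatrix, generate_mock_pssm
from afpkit.sequences import CANONICAL_ALPHABET, ProteinSequence, write_fasta

_N_AA = 20


def uniform_bias() -> np.ndarray:
    """The uniform composition vector (1/20 per residue)."""
    return np.full(_N_AA, 1.0 / _N_AA)


def shifted_bias(
    favored: str = "AGST", boost: float = 3.0
) -> np.ndarray:
    """A composition vector with ``favored`` residues ``boost`` times more
    likely than the rest (renormalized). The default favors the small
    residues common in ice-binding repeat motifs."""
    weights = np.ones(_N_AA)
    for ch in favored:
        weights[CANONICAL_ALPHABET.index(ch)] = boost
    return weights / weights.sum()


def disjoint_biases() -> tuple[np.ndarray, np.ndarray]:
    """Two bias vectors with disjoint support (first 10 vs last 10
    residues of the alphabet) — a perfectly separable pair."""
    pos = np.zeros(_N_AA)
    neg = np.zeros(_N_AA)
    pos[:10] = 0.1
    neg[10:] = 0.1
    return pos, neg


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class sequence dataset."""

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 150)
    bias_pos: np.ndarray = field(default_factory=lambda: shifted_bias())
    bias_neg: np.ndarray = field(default_factory=uniform_bias)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        for name, bias in (("bias_pos", self.bias_pos), ("bias_neg", self.bias_neg)):
            b = np.asarray(bias, dtype=float)
            object.__setattr__(self, name, b)
            if b.shape != (_N_AA,):
                raise ValueError(f"{name} must have 20 entries")
            if np.any(b < 0) or b.sum() == 0:
                raise ValueError(f"{name} is degenerate (negative or all-zero)")
            if abs(b.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {b.sum():.12g})")


def generate_dataset(
    spec: SyntheticSpec,
    with_pssms: bool = False,
) -> tuple[list[ProteinSequence], np.ndarray, Optional[dict[str, PSSMatrix]]]:
    """Draw a labeled dataset from ``spec``.

    Returns ``(sequences, labels, pssms)`` where labels are 1 for the
    positive class; ``pssms`` maps sequence id to a mock profile when
    ``with_pssms`` is set, else None. Fully deterministic given
    ``spec.seed`` (per-sequence PSSM seeds are derived from the same
    stream).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(CANONICAL_ALPHABET))
    lo, hi = spec.length_range
    sequences: list[ProteinSequence] = []
    labels: list[int] = []
    pssms: dict[str, PSSMatrix] = {}
    specs = [("pos", spec.n_pos, spec.bias_pos, 1), ("neg", spec.n_neg, spec.bias_neg, 0)]
    for prefix, n, bias, label in specs:
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(alphabet, size=length, p=bias))
            seq = ProteinSequence(id=f"{prefix}{i:04d}", residues=residues)
            sequences.append(seq)
            labels.append(label)
            if with_pssms:
                pssm_seed = int(rng.integers(0, 2**31))
                pssms[seq.id] = generate_mock_pssm(seq, seed=pssm_seed)
    return sequences, np.array(labels, dtype=int), (pssms if with_pssms else None)


def write_dataset(
    sequences: list[ProteinSequence],
    labels: np.ndarray,
    fasta_path: Union[str, Path],
    label_path: Union[str, Path],
    pssms: Optional[dict[str, PSSMatrix]] = None,
    pssm_dir: Optional[Union[str, Path]] = None,
) -> None:
    """Write FASTA + two-column (id, label) TSV, and optionally one ASCII
    PSSM file per sequence (named ``<id>.pssm``) into ``pssm_dir``."""
    from afpkit.pssm import write_pssm

    write_fasta(sequences, fasta_path)
    with open(label_path, "w", encoding="utf-8") as fh:
        for seq, y in zip(sequences, labels):
            fh.write(f"{seq.id}\t{int(y)}\n")
    if pssms is not None:
        if pssm_dir is None:
            raise ValueError("pssm_dir required when writing PSSMs")
        out = Path(pssm_dir)
        out.mkdir(parents=True, exist_ok=True)
        for seq_id, m in pssms.items():
            write_pssm(m, out / f"{seq_id}.pssm")
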
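"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the defining formulas with plain Python loops,
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import math

from afpkit.sequences import CANONICAL_ALPHABET


def dipeptide_brute(residues: str) -> list[float]:
    pairs = [(a, b) for a in CANONICAL_ALPHABET for b in CANONICAL_ALPHABET]
    out = []
    n_pairs = len(residues) - 1
    for a, b in pairs:
        count = 0
        for i in range(n_pairs):
            if residues[i] == a and residues[i + 1] == b:
                count += 1
        out.append(count / n_pairs)
    return out


def pseaac_brute(
    residues: str, omega: float, lam: int, scales
) -> list[float]:
    """Literal double-loop evaluation of the pseudo amino acid
    composition: normalized frequencies plus weighted correlation factors,
    all over the common denominator."""
    L = len(residues)
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}

    def prop(j: int, i: int) -> float:
        return float(scales[j][aa_index[residues[i]]])

    def big_theta(i: int, k: int) -> float:
        return sum((prop(j, i) - prop(j, k)) ** 2 for j in range(3)) / 3.0

    theta = []
    for d in range(1, lam + 1):
        total = 0.0
        for i in range(L - d):
            total += big_theta(i, i + d)
        theta.append(total / (L - d))

    freqs = [residues.count(aa) / L for aa in CANONICAL_ALPHABET]
    denom = sum(freqs) + omega * sum(theta)
    return [f / denom for f in freqs] + [omega * t / denom for t in theta]


def pssm400_brute(residue_column: str, scores) -> list[float]:
    """Position loop accumulating per-residue-type sums of squashed
    scores, then averaging; zero block for absent types."""
    sums = {aa: [0.0] * 20 for aa in CANONICAL_ALPHABET}
    counts = {aa: 0 for aa in CANONICAL_ALPHABET}
    for pos, res in enumerate(residue_column):
        counts[res] += 1
        for col in range(20):
            sums[res][col] += 1.0 / (1.0 + math.exp(-float(scores[pos][col])))
    out = []
    for aa in CANONICAL_ALPHABET:
        if counts[aa] == 0:
            out.extend([0.0] * 20)
        else:
            out.extend(v / counts[aa] for v in sums[aa])
    return out


def auc_brute(scores, y_true) -> float:
    """All-pairs Mann-Whitney statistic: fraction of (positive, negative)
    pairs ranked correctly, ties counted half."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
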
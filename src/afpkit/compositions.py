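"""Alignment-free sequence encoders.

Three encodings that map a variable-length protein sequence to a fixed
vector:

* amino-acid composition (AAC) — the 20 residue frequencies;
* dipeptide composition — the 400 adjacent ordered-pair frequencies;
* Chou's pseudo amino acid composition (PseAAC) — AAC augmented with
  ``lam`` sequence-order correlation factors theta(d), d = 1..lam, where
  theta(d) is the mean squared physicochemical-property difference between
  residues d positions apart, averaged over three standardized property
  scales (hydrophobicity, hydrophilicity, side-chain mass).

With weighting factor ``omega`` the PseAAC components are::

    p_i     = f(i)              / (sum_j f(j) + omega * sum_d theta(d))   i = 1..20
    p_20+d  = omega * theta(d)  / (sum_j f(j) + omega * sum_d theta(d))   d = 1..lam

so the full (20 + lam)-vector sums to 1. f(i) are the normalized residue
frequencies. At omega = 0 (or for a homopolymer, where all property
differences vanish) PseAAC reduces exactly to AAC padded with zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from afpkit.features import FeatureVector
from afpkit.sequences import AA_INDEX, CANONICAL_ALPHABET, ProteinSequence

_N_AA = 20


def _standardize(values: np.ndarray) -> np.ndarray:
    # population SD (ddof=0) over the 20 residues, the PseAAC convention
    mean = values.mean()
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("constant property scale cannot be standardized")
    return (values - mean) / sd


@dataclass(frozen=True)
class PropertyTable:
    """Three standardized amino-acid property scales for PseAAC.

    ``scales`` is a (3, 20) array in canonical alphabet order; each row has
    mean 0 and population SD 1 over the 20 residues. Rows are, in order,
    hydrophobicity, hydrophilicity, and side-chain mass. Alternative scales
    can be supplied through :meth:`from_raw`.
    """

    scales: np.ndarray

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        object.__setattr__(self, "scales", scales)
        if scales.shape != (3, _N_AA):
            raise ValueError(f"expected (3, 20) property array, got {scales.shape}")
        if not (
            np.allclose(scales.mean(axis=1), 0.0, atol=1e-9)
            and np.allclose(scales.std(axis=1, ddof=0), 1.0, atol=1e-9)
        ):
            raise ValueError("property scales must be standardized (mean 0, SD 1)")

    @classmethod
    def from_raw(
        cls,
        h1: Mapping[str, float],
        h2: Mapping[str, float],
        h3: Mapping[str, float],
    ) -> "PropertyTable":
        """Build a table from raw per-residue scales, standardizing each."""
        rows = []
        for scale in (h1, h2, h3):
            missing = [aa for aa in CANONICAL_ALPHABET if aa not in scale]
            if missing:
                raise ValueError(f"property scale missing residues: {missing}")
            rows.append(
                _standardize(
                    np.array([scale[aa] for aa in CANONICAL_ALPHABET], dtype=float)
                )
            )
        return cls(scales=np.vstack(rows))

    @classmethod
    def default(cls) -> "PropertyTable":
        """The canonical PseAAC triplet shipped with the package."""
        raw = json.loads(
            resources.files("afpkit.data")
            .joinpath("chou_properties.json")
            .read_text(encoding="utf-8")
        )
        return cls.from_raw(
            raw["hydrophobicity"], raw["hydrophilicity"], raw["side_chain_mass"]
        )


def _counts(seq: ProteinSequence) -> np.ndarray:
    counts = np.zeros(_N_AA)
    for ch in seq.residues:
        counts[AA_INDEX[ch]] += 1
    return counts


def aac(seq: ProteinSequence) -> FeatureVector:
    """Amino-acid composition: the 20 residue frequencies (sums to 1)."""
    values = _counts(seq) / seq.length
    return FeatureVector(scheme="aac", values=values, seq_id=seq.id)


def dipeptide(seq: ProteinSequence) -> FeatureVector:
    """Dipeptide composition: frequencies of the 400 ordered adjacent
    residue pairs, row-major in canonical order (sums to 1).

    Requires at least two residues; the denominator is the number of
    adjacent pairs, L - 1.
    """
    if seq.length < 2:
        raise ValueError(
            f"record {seq.id!r}: sequence too short for dipeptide composition "
            f"(L={seq.length}, need >= 2)"
        )
    counts = np.zeros((_N_AA, _N_AA))
    for a, b in zip(seq.residues, seq.residues[1:]):
        counts[AA_INDEX[a], AA_INDEX[b]] += 1
    values = counts.ravel() / (seq.length - 1)
    return FeatureVector(scheme="dipeptide", values=values, seq_id=seq.id)


def sequence_order_factors(
    seq: ProteinSequence, lam: int, props: PropertyTable
) -> np.ndarray:
    """The lam correlation factors theta(d), d = 1..lam.

    theta(d) averages, over all residue pairs d positions apart, the mean
    squared difference of the three standardized property values. All
    factors are nonnegative; a homopolymer yields all zeros.
    """
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if seq.length <= lam:
        raise ValueError(
            f"record {seq.id!r}: L={seq.length} <= lambda={lam}; lower lambda "
            "or use a longer sequence"
        )
    # (3, L) property profile of this sequence
    idx = np.fromiter((AA_INDEX[ch] for ch in seq.residues), dtype=int)
    profile = props.scales[:, idx]
    theta = np.empty(lam)
    for d in range(1, lam + 1):
        diff = profile[:, :-d] - profile[:, d:]
        theta[d - 1] = np.mean(diff**2, axis=0).mean()
    return theta


def pseaac(
    seq: ProteinSequence,
    omega: float = 0.1,
    lam: int = 30,
    props: Optional[PropertyTable] = None,
) -> FeatureVector:
    """Chou's pseudo amino acid composition: a (20 + lam)-vector.

    Parameters
    ----------
    omega
        Weighting factor balancing composition against sequence-order
        correlation (default 0.1).
    lam
        Number of correlation tiers (default 30, giving 50 features).
        Requires L >= lam + 1.
    props
        Property table; defaults to the shipped hydrophobicity /
        hydrophilicity / side-chain-mass triplet.
    """
    if omega < 0:
        raise ValueError(f"omega must be nonnegative, got {omega}")
    if props is None:
        props = PropertyTable.default()
    counts = _counts(seq)
    theta = sequence_order_factors(seq, lam, props)
    # Multiplying numerator and denominator of the frequency form by L
    # keeps integer counts in the numerator, so the omega = 0 (and
    # homopolymer) limit reduces to AAC bit-exactly.
    denom = counts.sum() + omega * seq.length * theta.sum()
    values = np.concatenate([counts, omega * seq.length * theta]) / denom
    return FeatureVector(scheme="pseaac", values=values, seq_id=seq.id)
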
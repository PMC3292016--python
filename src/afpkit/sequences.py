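"""FASTA I/O and the canonical amino-acid alphabet.

Every encoder in the toolkit indexes features by one fixed alphabet:
the 20 canonical one-letter codes in alphabetical order. PSI-BLAST PSSM
files use a different column order; the PSSM parser remaps to this one.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: code -> position in :data:`CANONICAL_ALPHABET`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}

#: Codes that appear in real databases but are not one of the 20 canonical
#: residues: ambiguity codes (B, J, X, Z), rare residues translated from
#: non-standard codons (O, U), and the stop symbol.
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ*")


class SequenceError(ValueError):
    """Invalid sequence content or malformed FASTA input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    id
        Record identifier (first whitespace-delimited token of the FASTA
        header).
    residues
        Residue string over the canonical 20-letter alphabet.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for ch in self.residues:
            if ch not in AA_INDEX:
                raise SequenceError(
                    f"record {self.id!r}: non-canonical residue {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        """Number of residues (L)."""
        return len(self.residues)


def sanitize(raw: str, policy: str = "strict", record_id: str = "?") -> str:
    """Normalize a raw residue string to the canonical alphabet.

    Uppercases and strips whitespace. Non-canonical codes (B, J, O, U, X,
    Z, ``*``) are rejected under ``strict`` and silently dropped (with a
    logged warning) under ``drop-unknown``.

    Raises
    ------
    SequenceError
        On an unknown policy, a non-canonical code under ``strict``, a
        character that is not an amino-acid code at all, or an empty
        result.
    """
    if policy not in ("strict", "drop-unknown"):
        raise ValueError(f"unknown sanitization policy {policy!r}")
    cleaned: list[str] = []
    dropped: list[str] = []
    for ch in raw:
        if ch.isspace():
            continue
        up = ch.upper()
        if up in AA_INDEX:
            cleaned.append(up)
        elif up in NON_CANONICAL:
            if policy == "strict":
                raise SequenceError(
                    f"record {record_id!r}: non-canonical residue {ch!r} "
                    "(use policy='drop-unknown' to remove such codes)"
                )
            dropped.append(up)
        else:
            raise SequenceError(
                f"record {record_id!r}: invalid character {ch!r}"
            )
    if dropped:
        logger.warning(
            "record %r: dropped %d non-canonical residue(s): %s",
            record_id, len(dropped), "".join(sorted(set(dropped))),
        )
    if not cleaned:
        raise SequenceError(
            f"record {record_id!r}: no canonical residues remain after "
            "sanitization"
        )
    return "".join(cleaned)


def _as_handle(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def read_fasta(
    source: Union[str, Path, TextIO], policy: str = "strict"
) -> list[ProteinSequence]:
    """Read a FASTA file or text stream into validated sequences.

    Record order is preserved; multi-line bodies are concatenated; the id
    is the first whitespace-delimited header token. ``policy`` controls
    how non-canonical residues are handled (see :func:`sanitize`).

    Raises
    ------
    SequenceError
        If the source holds no records or a record fails validation.
    """
    handle = _as_handle(source)
    close = isinstance(source, (str, Path))
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise SequenceError("no records found in FASTA input")
    out = []
    for rec in records:
        residues = sanitize(str(rec.seq), policy=policy, record_id=rec.id)
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def read_fasta_text(text: str, policy: str = "strict") -> list[ProteinSequence]:
    """:func:`read_fasta` over an in-memory string."""
    return read_fasta(io.StringIO(text), policy=policy)


def write_fasta(
    sequences: Iterable[ProteinSequence],
    dest: Union[str, Path, TextIO],
    width: int = 60,
) -> None:
    """Write sequences as FASTA, wrapping bodies at ``width`` columns."""
    handle: TextIO
    if isinstance(dest, (str, Path)):
        handle = open(dest, "w", encoding="utf-8")
        close = True
    else:
        handle = dest
        close = False
    try:
        for seq in sequences:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")
    finally:
        if close:
            handle.close()
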
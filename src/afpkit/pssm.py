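"""PSI-BLAST PSSM parsing and the PSSM-400 evolutionary-profile encoding.

A position-specific scoring matrix (PSSM) is the L x 20 table of log-odds
substitution scores that PSI-BLAST derives from an iterative profile
search; row i describes how conserved each amino acid is at sequence
position i. The PSSM-400 encoding aggregates these rows by the identity of
the query residue: for each of the 20 amino-acid types, the (squashed)
rows at positions holding that residue are averaged into a 20-vector, and
the 20 group vectors are concatenated — a fixed 400-vector regardless of
sequence length.

Raw log-odds are unbounded integers, so each score x is squashed through
the logistic function 1 / (1 + e^(-x)) before averaging, giving features
in [0, 1]. Types absent from the sequence contribute exact-zero blocks.
The squashing choice is recorded in trained-model metadata.

Running PSI-BLAST is the caller's responsibility: this module builds the
documented command lines (legacy blastpgp and modern psiblast dialects),
parses the ASCII output of either, and provides a deterministic mock
generator so the rest of the toolkit is testable without BLAST.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np

from afpkit.features import FeatureVector
from afpkit.sequences import AA_INDEX, CANONICAL_ALPHABET, ProteinSequence

#: Column order of PSI-BLAST ASCII output (both dialects).
PSSM_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: index into a native-order row -> index in canonical alphabetical order.
_NATIVE_TO_CANONICAL = np.array(
    [AA_INDEX[aa] for aa in PSSM_COLUMN_ORDER], dtype=int
)
#: canonical position -> native column holding that residue's score.
_CANONICAL_TO_NATIVE = np.argsort(_NATIVE_TO_CANONICAL)


class PSSMParseError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM input."""


@dataclass(frozen=True)
class PSSMatrix:
    """An L x 20 position-specific scoring matrix.

    ``scores`` columns are in canonical alphabetical order (remapped from
    PSI-BLAST's native order at parse time); ``residue_column`` holds the
    query residue at each position.
    """

    seq_id: str
    residue_column: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=int)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got {scores.shape}")
        if scores.shape[0] != len(self.residue_column):
            raise ValueError(
                f"{scores.shape[0]} score rows but "
                f"{len(self.residue_column)} residues"
            )
        if scores.shape[0] < 1:
            raise ValueError("empty PSSM")
        for ch in self.residue_column:
            if ch not in AA_INDEX:
                raise ValueError(f"non-canonical residue {ch!r} in PSSM")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def parse_pssm(
    source: Union[str, Path, TextIO], seq_id: str = ""
) -> PSSMatrix:
    """Parse a PSI-BLAST ASCII PSSM (legacy ``-Q`` or BLAST+
    ``-out_ascii_pssm`` dialect).

    Only the first 20-column block (log-odds scores) is used; the weighted
    observed percentages and trailing statistics are ignored. Columns are
    remapped from the native A R N D C Q E G H I L K M F P S T W Y V order
    to canonical alphabetical order.

    Raises
    ------
    PSSMParseError
        On an empty file, a missing header, a short or non-numeric score
        row (the message cites the line number).
    """
    if isinstance(source, (str, Path)):
        if not seq_id:
            seq_id = Path(source).stem
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    if not any(line.strip() for line in lines):
        raise PSSMParseError("empty PSSM file")

    # Locate the column-header line: 20 (legacy) or 40 (with percentage
    # block) single-letter tokens spelling the native residue order.
    header_idx: Optional[int] = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) in (20, 40) and all(
            len(t) == 1 and t in AA_INDEX for t in tokens
        ):
            if "".join(tokens[:20]) != PSSM_COLUMN_ORDER:
                raise PSSMParseError(
                    f"line {i + 1}: unexpected PSSM column order "
                    f"{''.join(tokens[:20])!r}"
                )
            header_idx = i
            break
    if header_idx is None:
        raise PSSMParseError("no PSSM column header line found")

    residues: list[str] = []
    rows: list[np.ndarray] = []
    expected_pos = 1
    for lineno, line in enumerate(
        lines[header_idx + 1 :], start=header_idx + 2
    ):
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # trailing K/Lambda statistics
        if int(tokens[0]) != expected_pos:
            raise PSSMParseError(
                f"line {lineno}: expected position {expected_pos}, "
                f"got {tokens[0]!r}"
            )
        if len(tokens) < 22:
            raise PSSMParseError(
                f"line {lineno}: expected residue plus 20 score columns, "
                f"got {len(tokens) - 2 if len(tokens) >= 2 else 0} scores"
            )
        residue = tokens[1]
        if len(residue) != 1 or residue.upper() not in AA_INDEX:
            raise PSSMParseError(
                f"line {lineno}: invalid residue code {residue!r}"
            )
        try:
            row = np.array([int(t) for t in tokens[2:22]], dtype=int)
        except ValueError as exc:
            raise PSSMParseError(
                f"line {lineno}: non-numeric score cell ({exc})"
            ) from None
        residues.append(residue.upper())
        rows.append(row)
        expected_pos += 1
    if not rows:
        raise PSSMParseError("no score rows found after header")

    native = np.vstack(rows)
    canonical = native[:, _CANONICAL_TO_NATIVE]
    return PSSMatrix(
        seq_id=seq_id, residue_column="".join(residues), scores=canonical
    )


def write_pssm(m: PSSMatrix, dest: Union[str, Path, TextIO]) -> None:
    """Write a PSSMatrix in the BLAST+ ASCII dialect (native column order,
    log-odds block plus a zero percentage block and trailing statistics),
    round-trippable through :func:`parse_pssm`."""
    native = m.scores[:, _NATIVE_TO_CANONICAL]
    buf = io.StringIO()
    buf.write(
        "\nLast position-specific scoring matrix computed, weighted "
        "observed percentages rounded down, information per position, "
        "and relative weight of gapless real matches to pseudocounts\n"
    )
    letters = "  ".join(PSSM_COLUMN_ORDER)
    buf.write("           " + letters + "   " + "   ".join(PSSM_COLUMN_ORDER) + "\n")
    for i, (res, row) in enumerate(zip(m.residue_column, native), start=1):
        scores = " ".join(f"{v:3d}" for v in row)
        pct = " ".join(f"{0:3d}" for _ in range(20))
        buf.write(f"{i:5d} {res}   {scores}  {pct}  0.00 0.00\n")
    buf.write("\n                      K         Lambda\n")
    buf.write("Standard Ungapped    0.1347     0.3176\n")
    buf.write("Standard Gapped      0.0410     0.2670\n")
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    else:
        dest.write(buf.getvalue())


def generate_mock_pssm(
    seq: ProteinSequence,
    seed: int,
    score_range: tuple[int, int] = (-8, 11),
    out_path: Optional[Union[str, Path]] = None,
) -> PSSMatrix:
    """Deterministic stand-in for a real PSI-BLAST profile.

    Synthetic: integer scores are drawn uniformly from ``score_range``
    (inclusive) with the query residue's own column biased upward so it is
    at least the row median, mimicking the self-conservation of real
    profiles. If ``out_path`` is given the matrix is also written in the
    BLAST+ ASCII dialect.
    """
    lo, hi = score_range
    if lo >= hi:
        raise ValueError(f"invalid score range {score_range}")
    rng = np.random.default_rng(seed)
    scores = rng.integers(lo, hi + 1, size=(seq.length, 20))
    for i, ch in enumerate(seq.residues):
        j = AA_INDEX[ch]
        med = np.median(scores[i])
        scores[i, j] = min(hi, int(max(med, scores[i, j])) + 3)
    m = PSSMatrix(seq_id=seq.id, residue_column=seq.residues, scores=scores)
    if out_path is not None:
        write_pssm(m, out_path)
    return m


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def pssm400(m: PSSMatrix, squash: str = "sigmoid") -> FeatureVector:
    """The 400-dimensional PSSM-400 encoding.

    Each score is squashed (``sigmoid`` by default, ``identity`` to keep
    raw log-odds), rows are grouped by the query residue, each group is
    averaged elementwise into a 20-vector (zero vector for residue types
    absent from the sequence), and the 20 group vectors are concatenated
    in canonical alphabet order.
    """
    if squash == "sigmoid":
        transformed = _sigmoid(m.scores.astype(float))
    elif squash == "identity":
        transformed = m.scores.astype(float)
    else:
        raise ValueError(f"unknown squashing function {squash!r}")
    idx = np.fromiter((AA_INDEX[ch] for ch in m.residue_column), dtype=int)
    blocks = np.zeros((20, 20))
    for a in range(20):
        mask = idx == a
        if mask.any():
            blocks[a] = transformed[mask].mean(axis=0)
    return FeatureVector(
        scheme="pssm400", values=blocks.ravel(), seq_id=m.seq_id
    )


def psiblast_command(
    seq_file: Union[str, Path],
    db: Union[str, Path],
    out_pssm: Union[str, Path],
    dialect: str = "modern",
) -> tuple[str, list[str]]:
    """The documented PSI-BLAST invocation for profile generation: three
    iterations with inclusion e-value threshold 0.0001.

    Returns ``(program, argument list)`` without executing anything.
    ``dialect`` is ``modern`` (BLAST+ ``psiblast``) or ``legacy``
    (``blastpgp``).
    """
    for name, p in (("seq_file", seq_file), ("db", db), ("out_pssm", out_pssm)):
        if not str(p):
            raise ValueError(f"{name} path must be non-empty")
    if dialect == "legacy":
        return "blastpgp", [
            "-i", str(seq_file),
            "-d", str(db),
            "-j", "3",
            "-h", "0.0001",
            "-Q", str(out_pssm),
        ]
    if dialect == "modern":
        return "psiblast", [
            "-query", str(seq_file),
            "-db", str(db),
            "-num_iterations", "3",
            "-inclusion_ethresh", "0.0001",
            "-out_ascii_pssm", str(out_pssm),
        ]
    raise ValueError(f"unknown dialect {dialect!r}")
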
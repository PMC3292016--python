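"""The fixed-length feature-vector container and its on-disk table formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

#: Expected dimensionality per encoding scheme. PseAAC is 20 + lambda and
#: therefore checked as >= 21 rather than against a constant.
SCHEME_DIMS: dict[str, int] = {"aac": 20, "dipeptide": 400, "pssm400": 400}


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric encoding of one sequence.

    ``scheme`` is one of ``aac``, ``dipeptide``, ``pseaac``, ``pssm400``.
    """

    scheme: str
    values: np.ndarray
    seq_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ValueError("feature values must be a 1-D vector")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature values in scheme {self.scheme!r}")
        if self.scheme in SCHEME_DIMS and len(vals) != SCHEME_DIMS[self.scheme]:
            raise ValueError(
                f"scheme {self.scheme!r} expects dimension "
                f"{SCHEME_DIMS[self.scheme]}, got {len(vals)}"
            )
        if self.scheme == "pseaac" and len(vals) < 21:
            raise ValueError("pseaac vectors have dimension 20 + lambda >= 21")

    @property
    def dim(self) -> int:
        return len(self.values)


def stack_features(features: Sequence[FeatureVector]) -> np.ndarray:
    """Stack same-scheme vectors into an (n, dim) matrix."""
    if not features:
        raise ValueError("no feature vectors given")
    schemes = {f.scheme for f in features}
    if len(schemes) > 1:
        raise ValueError(f"mixed feature schemes: {sorted(schemes)}")
    dims = {f.dim for f in features}
    if len(dims) > 1:
        raise ValueError(f"mixed feature dimensions: {sorted(dims)}")
    return np.vstack([f.values for f in features])


def write_feature_table(
    features: Iterable[FeatureVector], path: Union[str, Path]
) -> None:
    """Write features as a headered CSV: id, scheme, f0..f{dim-1}."""
    feats = list(features)
    mat = stack_features(feats)
    df = pd.DataFrame(mat, columns=[f"f{i}" for i in range(mat.shape[1])])
    df.insert(0, "scheme", [f.scheme for f in feats])
    df.insert(0, "id", [f.seq_id for f in feats])
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: Union[str, Path]) -> list[FeatureVector]:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    if "id" not in df.columns or "scheme" not in df.columns:
        raise ValueError(f"{path}: not a feature table (missing id/scheme columns)")
    value_cols = [c for c in df.columns if c not in ("id", "scheme")]
    return [
        FeatureVector(
            scheme=row["scheme"],
            values=row[value_cols].to_numpy(dtype=float),
            seq_id=str(row["id"]),
        )
        for _, row in df.iterrows()
    ]


def write_sparse(
    features: Iterable[FeatureVector],
    labels: Sequence[int],
    path: Union[str, Path],
) -> None:
    """Write features in the sparse ``label index:value`` format used by
    libsvm-style tools (1-based indices; zeros omitted)."""
    feats = list(features)
    if len(feats) != len(labels):
        raise ValueError("features and labels differ in length")
    with open(path, "w", encoding="utf-8") as fh:
        for f, y in zip(feats, labels):
            parts = [str(int(y))]
            for i, v in enumerate(f.values, start=1):
                if v != 0.0:
                    parts.append(f"{i}:{v:.12g}")
            fh.write(" ".join(parts) + "\n")
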
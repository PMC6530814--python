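"""Per-gene (row-wise) permutation of feature matrices.

Shuffling each row independently destroys TF-specific information while
preserving every gene-level quantity shared by all features of that gene
— exactly the confounders (peak count, length, signal) the diagnostics
are after.  For variants that carry the aggregate peak-feature columns,
only the TF columns are shuffled by default: permuting a 2-4 column
aggregate block would not remove TF identity, there is none in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PEAK_FEATURE_COLUMNS, FeatureMatrix

__all__ = ["PermutationScheme", "permute_rows", "default_scope"]


@dataclass(frozen=True)
class PermutationScheme:
    """Seed and column scope of the row-wise shuffle."""

    seed: int = 0
    scope: str = "tf_columns_only"  # or "all_columns"

    def __post_init__(self) -> None:
        if self.scope not in ("tf_columns_only", "all_columns"):
            raise ValueError(f"unknown scope {self.scope!r}")


def default_scope(variant: str) -> str:
    """tf_columns_only when the variant carries peak-feature columns."""
    return "tf_columns_only" if variant in ("CN", "DN", "DSN", "DPF", "DPFS") else "all_columns"


def permute_rows(matrix: FeatureMatrix, scheme: PermutationScheme) -> FeatureMatrix:
    """Shuffle the in-scope values of every row independently.

    One generator is seeded once and rows are permuted in row order, so
    the result is reproducible from the seed.  Column names stay in
    place; peak-feature columns are untouched under tf_columns_only.
    """
    if matrix.values.empty:
        raise ValueError("cannot permute an empty matrix")
    if scheme.scope == "tf_columns_only":
        in_scope = [c for c in matrix.values.columns if c not in PEAK_FEATURE_COLUMNS]
    else:
        in_scope = list(matrix.values.columns)
    if not in_scope:
        raise ValueError("no columns in permutation scope")

    rng = np.random.default_rng(scheme.seed)
    out = matrix.values.copy()
    block = out[in_scope].to_numpy()
    for i in range(block.shape[0]):
        block[i] = block[i, rng.permutation(block.shape[1])]
    out[in_scope] = block
    return FeatureMatrix(values=out, variant=matrix.variant)
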
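"""Laplacian normalization of the similarity layers.

The plain normalization divides each entry by the geometric mean of its row
and column sums.  The two-step layer normalizations first apply that step and
then rescale so that nonzero ROWS of the lncRNA layer sum to 1 (the score
matrix multiplies it on the right) while nonzero COLUMNS of the disease layer
sum to 1 (it multiplies the score matrix on the left).  The asymmetry is
deliberate and matched to the walk's update rule; no symmetric variant is
offered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "laplacian_normalize", "normalize_lncrna", "normalize_disease"]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Output of the two-step layer normalization; generally asymmetric."""

    values: np.ndarray
    ids: tuple[str, ...]
    role: str  # "LL" (row-stochastic on nonzero rows) or "LD" (column-stochastic)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("normalized matrix must be square")
        if self.role not in ("LL", "LD"):
            raise ValueError(f"unknown normalized role {self.role!r}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", tuple(self.ids))


def laplacian_normalize(m: np.ndarray) -> np.ndarray:
    """Normalize a symmetric matrix by M(i,j) / sqrt(rowsum_i * rowsum_j).

    Entries whose row or column sum is <= 0 are set to 0 (an empty or
    negative-weight neighborhood contributes nothing).  Output is symmetric.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    sums = m.sum(axis=1)
    ok = sums > 0
    inv_sqrt = np.zeros_like(sums)
    inv_sqrt[ok] = 1.0 / np.sqrt(sums[ok])
    out = m * inv_sqrt[:, None] * inv_sqrt[None, :]
    out[~ok, :] = 0.0
    out[:, ~ok] = 0.0
    return out


def _two_step(sim: SimilarityMatrix, expected_role: str, out_role: str) -> NormalizedMatrix:
    if sim.role != expected_role:
        raise ValueError(f"expected a {expected_role}-role matrix, got {sim.role!r}")
    s = sim.values
    nonzero = s != 0.0  # entries are constructed, not measured: exact-zero test
    row_sums = s.sum(axis=1)
    col_sums = s.sum(axis=0)
    # Step 1: divide by sqrt(rowsum * colsum) where defined; rows/columns whose
    # sum is <= 0 (possible only with negative expression correlations) are
    # zeroed with a warning -- a negative mass has no square root here.
    bad = (row_sums <= 0) | (col_sums <= 0)
    if bad.any() and nonzero[bad].any():
        logger.warning(
            "%s normalization: zeroing %d row(s)/column(s) with non-positive similarity mass",
            out_role,
            int(bad.sum()),
        )
    denom = np.sqrt(np.outer(np.where(bad, 0.0, row_sums), np.where(bad, 0.0, col_sums)))
    prime = np.zeros_like(s)
    valid = nonzero & (denom > 0)
    prime[valid] = s[valid] / denom[valid]
    # Step 2: make nonzero rows (LL) or columns (LD) sum to exactly 1.
    if out_role == "LL":
        norms = prime.sum(axis=1)
        axis_name, take = "row", lambda k: prime[k, :]
    else:
        norms = prime.sum(axis=0)
        axis_name, take = "column", lambda k: prime[:, k]
    out = np.zeros_like(prime)
    for k in range(s.shape[0]):
        vec = take(k)
        if not vec.any():
            continue
        if norms[k] == 0.0:
            raise ValueError(
                f"degenerate {axis_name} {sim.ids[k]!r}: nonzero similarities cancel to zero mass"
            )
        if out_role == "LL":
            out[k, :] = vec / norms[k]
        else:
            out[:, k] = vec / norms[k]
    return NormalizedMatrix(out, sim.ids, out_role)


def normalize_lncrna(sl: SimilarityMatrix) -> NormalizedMatrix:
    """Two-step normalization of the lncRNA layer; nonzero rows of LL sum to 1."""
    return _two_step(sl, "SL", "LL")


def normalize_disease(sd: SimilarityMatrix) -> NormalizedMatrix:
    """Two-step normalization of the disease layer; nonzero columns of LD sum to 1."""
    return _two_step(sd, "SD", "LD")
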
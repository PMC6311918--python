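"""Raw similarity matrices for the two network layers.

Two ingredients per layer: a Gaussian interaction-profile (GIP) kernel over
binary association profiles, and — for lncRNAs only — Spearman rank
correlation of expression profiles, fused with the kernel by a weight ``ew``.
Disease kernel similarities are additionally passed through a logistic
transform that spreads the (0, 1] kernel values over (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AssociationMatrix, ExpressionData

__all__ = [
    "SimilarityMatrix",
    "gip_kernel",
    "spearman_similarity",
    "combine_lncrna_similarity",
    "logistic_disease_similarity",
]

#: Valid roles a similarity matrix can carry through the pipeline.
ROLES = ("KL", "KD", "SPC", "SL", "SD")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix over one node set (lncRNAs or diseases)."""

    values: np.ndarray
    ids: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("similarity matrix must be square")
        if vals.shape[0] != len(self.ids):
            raise ValueError("identifier list does not match matrix size")
        if self.role not in ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")
        if not np.allclose(vals, vals.T, atol=1e-12, rtol=0.0):
            raise ValueError("similarity matrix must be symmetric to 1e-12")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", tuple(self.ids))


def gip_kernel(
    assoc: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over the rows or columns of ``assoc``.

    For ``axis="lncrna"`` the profiles are the columns of the association
    matrix; for ``axis="disease"`` they are the rows.  The bandwidth is
    ``gamma_prime`` divided by the mean squared profile norm, so the kernel is
    scale-adapted to the density of the association matrix:

        K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2),
        gamma   = gamma_prime / mean_i ||IP(i)||^2.
    """
    if axis == "lncrna":
        profiles = assoc.values.T
        ids = assoc.lncrna_ids
        role = "KL"
    elif axis == "disease":
        profiles = assoc.values
        ids = assoc.disease_ids
        role = "KD"
    else:
        raise ValueError(f"axis must be 'lncrna' or 'disease', got {axis!r}")
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("all-zero association matrix: kernel bandwidth is undefined")
    gamma = gamma_prime / mean_sq_norm
    # ||x - y||^2 via the Gram expansion; profiles are binary so this is exact
    # up to symmetric rounding.
    sq_norms = np.sum(profiles**2, axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-gamma * d2)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, ids, role)


def spearman_similarity(
    expr: ExpressionData, universe: tuple[str, ...] | list[str]
) -> SimilarityMatrix:
    """Spearman rank correlation of expression profiles over the full lncRNA universe.

    Entries involving an lncRNA without an expression profile are 0, as is the
    diagonal for unprofiled lncRNAs; profiled lncRNAs have unit self-similarity.
    A constant (zero-variance) profile correlates 0 with every partner — a flat
    profile carries no rank information.
    """
    universe = tuple(universe)
    n = len(universe)
    values = np.zeros((n, n))
    if expr.n_profiled > 0:
        missing = set(expr.lncrna_ids) - set(universe)
        if missing:
            raise ValueError(f"expression profiles outside the lncRNA universe: {sorted(missing)}")
        pos = {l: i for i, l in enumerate(universe)}
        idx = np.array([pos[l] for l in expr.lncrna_ids])
        ranks = np.apply_along_axis(stats.rankdata, 1, expr.values)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.atleast_2d(np.corrcoef(ranks))
        rho = np.nan_to_num(rho, nan=0.0)  # zero-variance profiles -> 0
        values[np.ix_(idx, idx)] = rho
        values[idx, idx] = 1.0
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, universe, "SPC")


def combine_lncrna_similarity(
    spc: SimilarityMatrix,
    kl: SimilarityMatrix,
    l1_mask: np.ndarray,
    ew: float,
) -> SimilarityMatrix:
    """Fuse expression similarity and kernel similarity into the lncRNA layer.

    Where both lncRNAs are profiled: ``ew * SPC + (1 - ew) * KL``; elsewhere
    the kernel alone.  ``ew = 0`` reproduces KL bit-for-bit.
    """
    if spc.ids != kl.ids:
        raise ValueError("SPC and KL must share the same lncRNA ordering")
    if not 0.0 <= ew <= 1.0:
        raise ValueError("ew must lie in [0, 1]")
    mask = np.asarray(l1_mask, dtype=bool)
    if mask.shape != (len(kl.ids),):
        raise ValueError("l1_mask length does not match the lncRNA universe")
    both = np.outer(mask, mask)
    values = kl.values.copy()
    values[both] = ew * spc.values[both] + (1.0 - ew) * kl.values[both]
    return SimilarityMatrix(values, kl.ids, "SL")


def logistic_disease_similarity(
    kd: SimilarityMatrix, c: float = -15.0, d: float = float(np.log(9999.0))
) -> SimilarityMatrix:
    """Entry-wise logistic transform 1 / (1 + exp(c * KD + d)) of the disease kernel.

    With the defaults c = -15, d = ln(9999), a kernel value of 0 maps to 1e-4
    and a kernel value of 1 maps to ~0.997, so all transformed similarities are
    strictly positive and the disease layer is fully connected.
    """
    if kd.role != "KD":
        raise ValueError(f"expected a KD-role matrix, got role {kd.role!r}")
    values = 1.0 / (1.0 + np.exp(c * kd.values + d))
    return SimilarityMatrix(values, kd.ids, "SD")
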
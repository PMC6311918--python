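"""Bi-random walk with restart on the heterogeneous network.

Two restart walks run in lock-step from the same seed distribution: one
propagates scores over the lncRNA layer (right-multiplication by LL), one over
the disease layer (left-multiplication by LD).  After every step the two score
matrices are averaged, and both walks continue from the averaged matrix, so
the iteration collapses to the single recurrence

    RT_t = (alpha / 2) * (RT_{t-1} @ LL + LD @ RT_{t-1}) + (1 - alpha) * Rt0

whose fixed point solves a Sylvester-type linear system.  Iteration stops when
the max-abs elementwise change drops below the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, RunConfig
from .normalization import NormalizedMatrix

__all__ = ["ScoreMatrix", "WalkResult", "init_scores", "birw_step", "run_birw"]


@dataclass(frozen=True)
class ScoreMatrix:
    """Disease x lncRNA real-valued score matrix, indexed like the association matrix."""

    values: np.ndarray
    disease_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.disease_ids), len(self.lncrna_ids)):
            raise ValueError("identifier lists do not match score matrix shape")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))

    def score(self, disease_id: str, lncrna_id: str) -> float:
        return float(
            self.values[self.disease_ids.index(disease_id), self.lncrna_ids.index(lncrna_id)]
        )


@dataclass(frozen=True)
class WalkResult:
    scores: ScoreMatrix
    iterations: int
    converged: bool
    final_delta: float


def init_scores(assoc: AssociationMatrix) -> ScoreMatrix:
    """Seed distribution: the association matrix divided by its number of 1-entries."""
    total = assoc.values.sum()
    if total == 0:
        raise ValueError("cannot seed the walk from an all-zero association matrix")
    return ScoreMatrix(assoc.values / total, assoc.disease_ids, assoc.lncrna_ids)


def _check_shapes(rt, ll: NormalizedMatrix, ld: NormalizedMatrix) -> None:
    nd, nl = rt.values.shape
    if ll.values.shape != (nl, nl):
        raise ValueError(f"lncRNA layer is {ll.values.shape}, expected ({nl}, {nl})")
    if ld.values.shape != (nd, nd):
        raise ValueError(f"disease layer is {ld.values.shape}, expected ({nd}, {nd})")
    if ll.role != "LL" or ld.role != "LD":
        raise ValueError("layers must carry roles LL and LD")


def birw_step(
    rt_prev: ScoreMatrix,
    ll: NormalizedMatrix,
    ld: NormalizedMatrix,
    rt0: ScoreMatrix,
    alpha: float,
) -> ScoreMatrix:
    """One averaged step of the two restart walks."""
    _check_shapes(rt_prev, ll, ld)
    if rt_prev.values.shape != rt0.values.shape:
        raise ValueError("rt_prev and rt0 shapes differ")
    rt_l = alpha * (rt_prev.values @ ll.values) + (1.0 - alpha) * rt0.values
    rt_d = alpha * (ld.values @ rt_prev.values) + (1.0 - alpha) * rt0.values
    return ScoreMatrix((rt_l + rt_d) / 2.0, rt_prev.disease_ids, rt_prev.lncrna_ids)


def run_birw(
    assoc: AssociationMatrix,
    ll: NormalizedMatrix,
    ld: NormalizedMatrix,
    cfg: RunConfig | None = None,
) -> WalkResult:
    """Iterate the averaged bi-random walk from the seed distribution to convergence.

    Returns the final score matrix with convergence metadata.  Non-convergence
    within ``cfg.max_iter`` (possible at alpha = 1, where the restart term
    vanishes) is reported via the ``converged`` flag rather than raised, so an
    evaluation harness can proceed and report.
    """
    cfg = cfg or RunConfig()
    rt0 = init_scores(assoc)
    _check_shapes(rt0, ll, ld)
    current = rt0.values
    delta = np.inf
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        nxt = (
            cfg.alpha / 2.0 * (current @ ll.values + ld.values @ current)
            + (1.0 - cfg.alpha) * rt0.values
        )
        if not np.isfinite(nxt).all():
            raise FloatingPointError(
                f"bi-random walk diverged to non-finite values at iteration {iterations}"
            )
        delta = float(np.max(np.abs(nxt - current)))
        current = nxt
        if delta < cfg.tol:
            break
    converged = delta < cfg.tol
    scores = ScoreMatrix(current, assoc.disease_ids, assoc.lncrna_ids)
    return WalkResult(scores=scores, iterations=iterations, converged=converged, final_delta=delta)
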
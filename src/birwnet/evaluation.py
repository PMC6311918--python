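"""Leave-one-out cross-validation, ROC/AUC, and per-disease candidate ranking.

LOOCV withholds each known association in turn, rebuilds BOTH similarity
layers from the modified association matrix (withholding an association
changes the interaction profiles, hence the kernels), reruns the walk, and
records the rank of the withheld pair's score among all pairs unknown to the
modified matrix, pooled globally.  Ranks use the average-tie convention so the
resulting AUC matches the Mann-Whitney statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

from .io import AssociationMatrix, ExpressionData, RunConfig
from .pipeline import build_layers
from .walk import ScoreMatrix, run_birw

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "loocv", "roc_auc", "top_k_candidates", "alpha_sweep"]

#: scorer signature: (masked association matrix, expression, config) -> ScoreMatrix
Scorer = Callable[[AssociationMatrix, ExpressionData, RunConfig], ScoreMatrix]


@dataclass(frozen=True)
class EvalResult:
    """Outcome of LOOCV: per-fold ranks, the ROC curve, and its trapezoidal AUC."""

    ranks: np.ndarray  # one average-tie rank per held-out association, 1 = best
    roc_points: np.ndarray  # (n_points, 2) array of (FPR, TPR), sorted by FPR
    auc: float
    n_folds: int
    n_candidates: int  # candidate (unknown) pairs per fold, excluding the held-out one

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc_points, columns=["fpr", "tpr"])


def _default_scorer(assoc: AssociationMatrix, expr: ExpressionData, cfg: RunConfig) -> ScoreMatrix:
    layers = build_layers(assoc, expr, cfg)
    result = run_birw(assoc, layers.ll, layers.ld, cfg)
    if not result.converged:
        logger.warning(
            "walk did not converge within %d iterations (final delta %.3g)",
            result.iterations,
            result.final_delta,
        )
    return result.scores


def loocv(
    assoc: AssociationMatrix,
    expr: ExpressionData | None = None,
    cfg: RunConfig | None = None,
    scorer: Scorer | None = None,
) -> EvalResult:
    """Leave-one-out cross-validation over every known association.

    For each fold the held-out entry is zeroed, similarities are fully
    recomputed from the modified matrix, the walk is rerun, and the held-out
    pair's score is ranked (average ties) among all pairs that are unknown to
    the modified matrix.  The ROC sweeps the rank threshold: sensitivity is
    the fraction of held-out associations ranked at or above the cutoff,
    1 - specificity the mean fraction of candidate pairs ranked above it.

    ``scorer`` replaces the propagation step (similarity rebuild + walk) and
    exists for calibration controls such as random or oracle scorers.
    """
    cfg = cfg or RunConfig()
    expr = expr if expr is not None else ExpressionData.empty()
    scorer = scorer or _default_scorer
    edges = np.argwhere(assoc.values == 1.0)
    if len(edges) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    ranks: list[float] = []
    n_unknown = None
    for i, j in edges:
        masked_values = assoc.values.copy()
        masked_values[i, j] = 0.0
        if not masked_values.any():
            logger.warning("fold (%d, %d) leaves an all-zero matrix; skipped", i, j)
            continue
        masked = AssociationMatrix(masked_values, assoc.disease_ids, assoc.lncrna_ids)
        rt = scorer(masked, expr, cfg)
        pool = rt.values[masked_values == 0.0]  # held-out pair included
        target = rt.values[i, j]
        greater = int(np.sum(pool > target))
        ties = int(np.sum(pool == target))  # includes the held-out pair itself
        ranks.append(greater + (ties + 1) / 2.0)
        n_unknown = pool.size
    ranks_arr = np.asarray(ranks)
    n_candidates = int(n_unknown) - 1  # exclude the held-out pair itself
    roc_points, auc = _roc_from_ranks(ranks_arr, n_candidates)
    return EvalResult(
        ranks=ranks_arr,
        roc_points=roc_points,
        auc=auc,
        n_folds=len(ranks_arr),
        n_candidates=n_candidates,
    )


def _roc_from_ranks(ranks: np.ndarray, n_candidates: int) -> tuple[np.ndarray, float]:
    """ROC over rank cutoffs k = 0..n_candidates+1 and its trapezoidal AUC."""
    ks = np.arange(0, n_candidates + 2, dtype=float)
    hit = ranks[None, :] <= ks[:, None]
    tpr = hit.mean(axis=1)
    neg_leq = np.clip(ks[:, None] - hit, 0.0, n_candidates)
    fpr = neg_leq.mean(axis=1) / n_candidates
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def roc_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for a set of positive vs negative scores.

    Thresholds are all distinct observed scores; tied positive/negative scores
    contribute half credit, so the AUC equals the normalized Mann-Whitney U
    statistic.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_skmetrics.auc(fpr, tpr))


def top_k_candidates(
    rt: ScoreMatrix, assoc: AssociationMatrix, disease_id: str, k: int
) -> list[tuple[str, float, int]]:
    """The k highest-scoring candidate lncRNAs (unknown pairs) for one disease.

    Known associations are excluded from candidacy; ties break by lncRNA
    identifier.  Returns (lncrna_id, score, rank) triples, rank 1 = best.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if disease_id not in rt.disease_ids:
        raise KeyError(f"unknown disease identifier {disease_id!r}")
    i = rt.disease_ids.index(disease_id)
    ai = assoc.disease_ids.index(disease_id)
    candidates = [
        (lnc, float(rt.values[i, j]))
        for j, lnc in enumerate(rt.lncrna_ids)
        if assoc.values[ai, assoc.lncrna_ids.index(lnc)] == 0.0
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    if k > len(candidates):
        logger.warning(
            "requested top %d but only %d candidate lncRNAs exist for %s",
            k,
            len(candidates),
            disease_id,
        )
    return [(lnc, score, rank) for rank, (lnc, score) in enumerate(candidates[:k], start=1)]


def alpha_sweep(
    assoc: AssociationMatrix,
    expr: ExpressionData | None,
    cfg: RunConfig | None,
    alphas: Sequence[float],
) -> tuple[pd.DataFrame, float]:
    """LOOCV AUC for each propagation weight alpha; returns the table and the argmax."""
    if len(alphas) == 0:
        raise ValueError("alphas must be nonempty")
    cfg = cfg or RunConfig()
    rows = []
    for alpha in alphas:
        sweep_cfg = RunConfig(
            alpha=float(alpha),
            ew=cfg.ew,
            gamma_l_prime=cfg.gamma_l_prime,
            gamma_d_prime=cfg.gamma_d_prime,
            c=cfg.c,
            d=cfg.d,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
        )
        result = loocv(assoc, expr, sweep_cfg)
        rows.append({"alpha": float(alpha), "auc": result.auc})
    table = pd.DataFrame(rows)
    best_alpha = float(table.loc[table["auc"].idxmax(), "alpha"])
    return table, best_alpha
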
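"""End-to-end pipeline: associations (+ optional expression) -> prediction scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, ExpressionData, RunConfig
from .normalization import NormalizedMatrix, normalize_disease, normalize_lncrna
from .similarity import (
    SimilarityMatrix,
    combine_lncrna_similarity,
    gip_kernel,
    logistic_disease_similarity,
    spearman_similarity,
)
from .walk import WalkResult, run_birw

__all__ = ["NetworkLayers", "build_layers", "predict"]


@dataclass(frozen=True)
class NetworkLayers:
    """All intermediate matrices of the heterogeneous-network construction."""

    kl: SimilarityMatrix
    kd: SimilarityMatrix
    spc: SimilarityMatrix
    sl: SimilarityMatrix
    sd: SimilarityMatrix
    ll: NormalizedMatrix
    ld: NormalizedMatrix


def build_layers(
    assoc: AssociationMatrix,
    expr: ExpressionData | None = None,
    cfg: RunConfig | None = None,
) -> NetworkLayers:
    """Construct and normalize both similarity layers from the association matrix.

    With no expression data (or ``ew = 0``) the lncRNA layer reduces to the
    interaction-profile kernel alone.
    """
    cfg = cfg or RunConfig()
    expr = expr if expr is not None else ExpressionData.empty()
    kl = gip_kernel(assoc, axis="lncrna", gamma_prime=cfg.gamma_l_prime)
    kd = gip_kernel(assoc, axis="disease", gamma_prime=cfg.gamma_d_prime)
    spc = spearman_similarity(expr, assoc.lncrna_ids)
    profiled = set(expr.lncrna_ids)
    l1_mask = np.array([l in profiled for l in assoc.lncrna_ids])
    sl = combine_lncrna_similarity(spc, kl, l1_mask, cfg.ew)
    sd = logistic_disease_similarity(kd, c=cfg.c, d=cfg.d)
    return NetworkLayers(
        kl=kl, kd=kd, spc=spc, sl=sl, sd=sd, ll=normalize_lncrna(sl), ld=normalize_disease(sd)
    )


def predict(
    assoc: AssociationMatrix,
    expr: ExpressionData | None = None,
    cfg: RunConfig | None = None,
) -> WalkResult:
    """Score every disease-lncRNA pair by the bi-random walk on the full network."""
    cfg = cfg or RunConfig()
    layers = build_layers(assoc, expr, cfg)
    return run_birw(assoc, layers.ll, layers.ld, cfg)
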
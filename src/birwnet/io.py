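"""Reading and writing association tables, expression matrices, scores and run configs.

All downstream matrices index rows/columns by the identifier orders stored on
:class:`AssociationMatrix`; identifier order is fixed at read time (first
appearance for edge lists, file order for dense tables) and is the single
source of truth thereafter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "ExpressionData",
    "RunConfig",
    "read_associations",
    "read_expression",
    "write_scores",
    "read_scores",
    "read_config",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary disease x lncRNA adjacency with identifier labels.

    ``values[i, j] == 1`` iff disease ``disease_ids[i]`` is known to associate
    with lncRNA ``lncrna_ids[j]``.  The i-th row is the disease's interaction
    profile; the j-th column is the lncRNA's interaction profile.
    """

    values: np.ndarray
    disease_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("association matrix must be at least 1x1")
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must all be 0 or 1")
        if vals.shape != (len(self.disease_ids), len(self.lncrna_ids)):
            raise ValueError("identifier lists do not match matrix shape")
        for ids, what in ((self.disease_ids, "disease"), (self.lncrna_ids, "lncRNA")):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {what} identifiers")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))

    @property
    def n_diseases(self) -> int:
        return self.values.shape[0]

    @property
    def n_lncrnas(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Known associations as (disease_id, lncrna_id) pairs in row-major order."""
        ii, jj = np.nonzero(self.values)
        return [(self.disease_ids[i], self.lncrna_ids[j]) for i, j in zip(ii, jj)]


@dataclass(frozen=True)
class ExpressionData:
    """Real-valued expression profiles for the subset of lncRNAs that have them.

    ``m = 0`` (no profiled lncRNA) is legal: the pipeline then falls back to the
    interaction-profile kernel alone.  A correlation needs at least two tissues,
    so ``t >= 2`` whenever ``m > 0``.
    """

    values: np.ndarray
    lncrna_ids: tuple[str, ...]
    tissue_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).reshape(
            len(self.lncrna_ids), len(self.tissue_ids)
        )
        if len(self.lncrna_ids) > 0 and len(self.tissue_ids) < 2:
            raise ValueError("expression data needs >= 2 tissues when any lncRNA is profiled")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA identifiers in expression data")
        if len(set(self.tissue_ids)) != len(self.tissue_ids):
            raise ValueError("duplicate tissue identifiers in expression data")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "tissue_ids", tuple(self.tissue_ids))

    @property
    def n_profiled(self) -> int:
        return len(self.lncrna_ids)

    @classmethod
    def empty(cls) -> "ExpressionData":
        return cls(np.zeros((0, 0)), (), ())


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the similarity construction and the walk.

    alpha
        Propagation weight; ``1 - alpha`` is the restart probability returned
        to the seed distribution at every step.
    ew
        Weight of expression similarity in the lncRNA similarity fusion.
    gamma_l_prime, gamma_d_prime
        Kernel-bandwidth base parameters of the Gaussian interaction-profile
        kernels; the effective bandwidth divides by the mean squared profile
        norm.
    c, d
        Logistic transform parameters for disease similarity.
    tol
        Convergence threshold on the max-abs change between successive score
        matrices.
    """

    alpha: float = 0.9
    ew: float = 0.5
    gamma_l_prime: float = 1.0
    gamma_d_prime: float = 1.0
    c: float = -15.0
    d: float = field(default_factory=lambda: math.log(9999.0))
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.ew <= 1.0:
            raise ValueError("ew must lie in [0, 1]")
        if self.gamma_l_prime <= 0 or self.gamma_d_prime <= 0:
            raise ValueError("kernel bandwidth bases must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


def _parse_binary(token: str, where: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"{where}: non-numeric value {token!r}") from None
    if value not in (0.0, 1.0):
        raise ValueError(f"{where}: association values must be 0 or 1, got {token!r}")
    return value


def read_associations(path: str | Path, format: str = "edge-list") -> AssociationMatrix:
    """Read a binary association table.

    ``format="edge-list"``: TSV rows ``disease_id<TAB>lncrna_id[<TAB>weight]``
    with weight in {0, 1}; duplicate edges collapse to a single 1 and
    identifiers are ordered by first appearance.

    ``format="dense"``: TSV with a header row of lncRNA ids and a first column
    of disease ids; identifier order is file order.
    """
    path = Path(path)
    if format == "edge-list":
        disease_ids: list[str] = []
        lncrna_ids: list[str] = []
        edges: list[tuple[str, str, float]] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) not in (2, 3):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(parts)}"
                    )
                dis, lnc = parts[0].strip(), parts[1].strip()
                if not dis or not lnc:
                    raise ValueError(f"{path}:{lineno}: empty identifier")
                weight = 1.0
                if len(parts) == 3:
                    weight = _parse_binary(parts[2].strip(), f"{path}:{lineno}")
                if dis not in disease_ids:
                    disease_ids.append(dis)
                if lnc not in lncrna_ids:
                    lncrna_ids.append(lnc)
                edges.append((dis, lnc, weight))
        if not edges:
            raise ValueError(f"{path}: no association rows found")
        values = np.zeros((len(disease_ids), len(lncrna_ids)))
        drow = {d: i for i, d in enumerate(disease_ids)}
        lcol = {l: j for j, l in enumerate(lncrna_ids)}
        for dis, lnc, weight in edges:
            if weight == 1.0:
                values[drow[dis], lcol[lnc]] = 1.0
        return AssociationMatrix(values, tuple(disease_ids), tuple(lncrna_ids))
    if format == "dense":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy(dtype=float)
        if not np.isin(values, (0.0, 1.0)).all():
            bad = values[~np.isin(values, (0.0, 1.0))][0]
            raise ValueError(f"{path}: dense association value {bad!r} is not 0 or 1")
        return AssociationMatrix(
            values, tuple(str(d) for d in frame.index), tuple(str(l) for l in frame.columns)
        )
    raise ValueError(f"unknown association format {format!r}")


def read_expression(path: str | Path, assoc: AssociationMatrix) -> ExpressionData:
    """Read an lncRNA x tissue expression TSV, keeping only lncRNAs known to ``assoc``.

    Rows whose identifier is not in the association universe are dropped with a
    warning (expression panels are routinely supersets of the association set).
    An empty file yields an empty :class:`ExpressionData`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return ExpressionData.empty()
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-numeric or missing expression value")
    known = set(assoc.lncrna_ids)
    keep = [str(i) in known for i in frame.index]
    n_dropped = len(keep) - sum(keep)
    if n_dropped:
        logger.warning(
            "dropping %d expression profile(s) for lncRNAs absent from the association matrix",
            n_dropped,
        )
    frame = frame.loc[keep]
    if frame.shape[0] == 0:
        return ExpressionData.empty()
    return ExpressionData(
        frame.to_numpy(dtype=float),
        tuple(str(i) for i in frame.index),
        tuple(str(t) for t in frame.columns),
    )


def write_scores(rt, path: str | Path, known: np.ndarray | None = None) -> None:
    """Write a score matrix as long-format TSV: disease, lncRNA, score, known flag.

    Rows are grouped by disease (in matrix order) and sorted by descending
    score within each disease; scores are printed with 17 significant digits so
    a read-back is bit-identical.  ``known`` (an association matrix of the same
    shape) fills the known_flag column; it defaults to all zeros.
    """
    values = np.asarray(rt.values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("score matrix contains non-finite entries")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("disease_id\tlncrna_id\tscore\tknown_flag\n")
        for i, dis in enumerate(rt.disease_ids):
            order = np.argsort(-values[i], kind="stable")
            for j in order:
                flag = int(known[i, j]) if known is not None else 0
                fh.write(f"{dis}\t{rt.lncrna_ids[j]}\t{values[i, j]:.17g}\t{flag}\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a long-format score TSV back as a DataFrame."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"disease_id": str, "lncrna_id": str},
        float_precision="round_trip",
    )


def read_config(path: str | Path) -> RunConfig:
    """Read a run configuration from a flat ``key: value`` / ``key=value`` file."""
    text = Path(path).read_text()
    if "=" in text and ":" not in text:
        text = "\n".join(
            line.replace("=", ": ", 1) for line in text.splitlines() if line.strip()
        )
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    known_fields = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known_fields
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "max_iter" in raw:
        raw["max_iter"] = int(raw["max_iter"])
    return RunConfig(**{k: float(v) if k != "max_iter" else v for k, v in raw.items()})


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write an association matrix as a canonical edge-list TSV."""
    with Path(path).open("w") as fh:
        for dis, lnc in assoc.edges():
            fh.write(f"{dis}\t{lnc}\n")


def write_expression(expr: ExpressionData, path: str | Path) -> None:
    """Write expression profiles as an lncRNA x tissue TSV."""
    frame = pd.DataFrame(expr.values, index=list(expr.lncrna_ids), columns=list(expr.tissue_ids))
    frame.to_csv(path, sep="\t", index_label="lncrna_id")
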
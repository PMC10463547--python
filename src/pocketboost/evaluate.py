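"""Metrics and the nested cross-validation experiment harness.

Two layers of cross-validation are involved and must not be confused.  The
outer k-fold CV measures generalization: each outer training partition gets
its own grid search (itself an internal k-fold CV on that partition only),
the winning configuration is refit on the whole partition, and Pearson R and
RMSE are computed on the held-out outer fold.  Reported means are arithmetic
means of the per-fold values, not pooled-residual statistics.

Ablation reports run the same outer folds over three feature blocks —
ligand descriptors only, protein composition only, and both concatenated —
so block comparisons are paired.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .dataset import Dataset
from .errors import UndefinedCorrelationError
from .featurize import block_columns

logger = logging.getLogger(__name__)

DEFAULT_BLOCKS = ("ligand_only", "protein_only", "combined")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson_r(y, yhat) -> float:
    """Product-moment correlation; refuses zero-variance input."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("pearson_r needs two equal-length 1-d vectors")
    if y.size < 2:
        raise ValueError("pearson_r needs at least 2 points")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(y, yhat).statistic)


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("rmse needs two equal-length non-empty 1-d vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    fold_id: int
    pearson_r: float
    rmse: float


@dataclass
class EvalReport:
    """Per-fold and mean metrics for each evaluated feature block."""

    per_fold: dict[str, list[FoldMetrics]]
    dataset_info: dict = field(default_factory=dict)
    fold_assignment_hash: str = ""

    def mean(self, block: str) -> tuple[float, float]:
        folds = self.per_fold[block]
        return (
            float(np.mean([f.pearson_r for f in folds])),
            float(np.mean([f.rmse for f in folds])),
        )

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(self.per_fold)

    def to_markdown(self) -> str:
        """Render per-fold rows plus an Average row as 'R/RMSE' to 3 decimals."""
        blocks = self.blocks
        lines = ["| Fold | " + " | ".join(blocks) + " |",
                 "|" + "---|" * (len(blocks) + 1)]
        n_folds = len(next(iter(self.per_fold.values())))
        for i in range(n_folds):
            cells = [
                f"{self.per_fold[b][i].pearson_r:.3f}/{self.per_fold[b][i].rmse:.3f}"
                for b in blocks
            ]
            fold_id = self.per_fold[blocks[0]][i].fold_id
            lines.append(f"| {fold_id} | " + " | ".join(cells) + " |")
        means = [f"{self.mean(b)[0]:.3f}/{self.mean(b)[1]:.3f}" for b in blocks]
        lines.append("| Average | " + " | ".join(means) + " |")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "dataset_info": self.dataset_info,
            "fold_assignment_hash": self.fold_assignment_hash,
            "blocks": {
                b: {
                    "per_fold": [
                        {"fold": f.fold_id, "pearson_r": f.pearson_r, "rmse": f.rmse}
                        for f in folds
                    ],
                    "mean_pearson_r": self.mean(b)[0],
                    "mean_rmse": self.mean(b)[1],
                }
                for b, folds in self.per_fold.items()
            },
        }


def _fold_hash(folds) -> str:
    h = hashlib.sha256()
    for _, test_idx in folds:
        h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def _outer_folds(n: int, k: int, seed: int):
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if n // k < 2:
        raise ValueError("each outer fold needs at least 2 test rows for Pearson R")
    return list(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)))


def _run_block(data: Dataset, folds, grid, inner_k: int, seed: int, n_jobs: int):
    from . import model as m  # local import: model depends on this module's metrics

    grid = grid or m.HyperGrid.reduced()
    results = []
    for fold_id, (tr, te) in enumerate(folds, start=1):
        train_part = data.subset(tr)
        spec = m.grid_search(train_part, grid, k=inner_k, seed=seed + fold_id, n_jobs=n_jobs)
        fitted = m.train(train_part, spec, seed=seed + fold_id, n_jobs=n_jobs)
        pred = fitted.predict(data.X[te], data.feature_names)
        results.append(FoldMetrics(fold_id, pearson_r(data.y[te], pred), rmse(data.y[te], pred)))
    return results


def cross_validate(
    data: Dataset, k: int = 5, seed: int = 0, grid=None, inner_k: int = 5,
    n_jobs: int = 1,
) -> EvalReport:
    """Outer k-fold CV with a fresh grid search per outer training partition."""
    folds = _outer_folds(len(data), k, seed)
    per_fold = {"combined": _run_block(data, folds, grid, inner_k, seed, n_jobs)}
    return EvalReport(
        per_fold=per_fold,
        dataset_info={"n_rows": len(data), "k": k, "seed": seed},
        fold_assignment_hash=_fold_hash(folds),
    )


def ablation_report(
    data: Dataset, blocks=DEFAULT_BLOCKS, k: int = 5, seed: int = 0, grid=None,
    inner_k: int = 5, n_jobs: int = 1,
) -> EvalReport:
    """Evaluate feature blocks under identical outer folds (paired design)."""
    folds = _outer_folds(len(data), k, seed)
    per_fold = {}
    for block in blocks:
        cols = block_columns(data.feature_names, block)
        sliced = Dataset(
            ids=data.ids,
            X=data.X[:, cols],
            y=data.y,
            feature_names=tuple(data.feature_names[i] for i in cols),
        )
        per_fold[block] = _run_block(sliced, folds, grid, inner_k, seed, n_jobs)
    n_proteins = len({pid.split(":", 1)[0] for pid in data.ids})
    return EvalReport(
        per_fold=per_fold,
        dataset_info={"n_rows": len(data), "n_proteins": n_proteins, "k": k, "seed": seed},
        fold_assignment_hash=_fold_hash(folds),
    )
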
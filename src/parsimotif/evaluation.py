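"""Classification-based assessment of motif discovery.

Whole sequences are classified foreground (ZOOPS: may contain a site)
versus background (homogeneous Markov model trained on the union of
positive and negative training data).  Since both models share the
flanking/background parameters, any gain in classification accuracy is
attributable to the motif model.  Performance is summarized as sensitivity
at a fixed specificity (99% in the reference setting) and AUC-ROC; a
seeded, stratified k-fold cross-validation sweeps the structure prior
kappa to pick the model complexity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .markov import HomogeneousMarkovModel, fit_homogeneous_mm, leaf_statistics
from .zoops import ZOOPSConfig, fit_zoops_em, zoops_log_likelihood_many

__all__ = [
    "ScorePair",
    "CVResult",
    "train_background",
    "score_test_set",
    "sensitivity_at_specificity",
    "auc_roc",
    "cross_validate_kappa",
    "DEFAULT_KAPPA_GRID",
]

# log2(kappa) grid spanning the range where optimal complexities live
DEFAULT_KAPPA_GRID = [-14, -12, -10, -9, -8, -7, -6, -5.5, -5, -4.5, -4, -3, -2, -1, 0]


@dataclass
class ScorePair:
    id: str
    label: str  # "positive" | "negative"
    score: float  # log P_fg(x) - log P_bg(x)


@dataclass
class CVResult:
    log2_kappa: float
    fold_sensitivities: list[float]
    fold_leaves: list[float]

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivities))

    @property
    def se_sensitivity(self) -> float:
        k = len(self.fold_sensitivities)
        return float(np.std(self.fold_sensitivities, ddof=1) / math.sqrt(k)) if k > 1 else 0.0

    @property
    def mean_leaves(self) -> float:
        return float(np.mean(self.fold_leaves))


def train_background(train_pos, train_neg, order: int = 2, ess: float = 4.0) -> HomogeneousMarkovModel:
    """Homogeneous MM on the union of both training sets.

    The same model serves as the classification background and as the
    flanking submodel of the foreground ZOOPS model.
    """
    return fit_homogeneous_mm(list(train_pos) + list(train_neg), order, ess)


def score_test_set(
    fg_model, bg_model: HomogeneousMarkovModel, records, label: str = "unlabeled"
) -> list[ScorePair]:
    """Log-likelihood-ratio scores, foreground (ZOOPS) vs background."""
    fg = zoops_log_likelihood_many(fg_model, records)
    bg = np.array([bg_model.log_prob(r.seq if hasattr(r, "seq") else r) for r in records])
    return [
        ScorePair(id=getattr(r, "id", str(i)), label=label, score=float(fg[i] - bg[i]))
        for i, r in enumerate(records)
    ]


def _score_values(fg_model, bg_model, records) -> np.ndarray:
    fg = zoops_log_likelihood_many(fg_model, records)
    bg = np.array([bg_model.log_prob(r.seq if hasattr(r, "seq") else r) for r in records])
    return fg - bg


def sensitivity_at_specificity(pos_scores, neg_scores, specificity: float = 0.99) -> float:
    """Fraction of positives above the empirical specificity threshold.

    The threshold t is the smallest score such that at least
    ``ceil(specificity * n_neg)`` negative scores are <= t (ceiling/type-1
    empirical quantile); sensitivity counts positives strictly above t.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    if not (0.0 < specificity < 1.0):
        raise ValueError("specificity must be in (0, 1)")
    k = math.ceil(specificity * neg.size)
    t = np.sort(neg)[k - 1]
    return float((pos > t).mean())


def auc_roc(pos_scores, neg_scores) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _stratified_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def cross_validate_kappa(
    train_pos,
    train_neg,
    kappa_grid=None,
    folds: int = 10,
    config: ZOOPSConfig | None = None,
    seed: int = 0,
    specificity: float = 0.99,
    bg_order: int = 2,
) -> tuple[list[CVResult], float]:
    """Seeded k-fold CV over a log2(kappa) grid; returns results + selection.

    Per fold: background trained on the union of the in-fold training
    data, ZOOPS-EM on the in-fold positives, evaluation on the held-out
    fold.  Selection is the grid value with the highest mean sensitivity;
    ties go to the smaller mean leaf count.
    """
    kappa_grid = list(kappa_grid) if kappa_grid is not None else list(DEFAULT_KAPPA_GRID)
    if not kappa_grid:
        raise ValueError("empty kappa grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    base = config or ZOOPSConfig()
    pos = list(train_pos)
    neg = list(train_neg)
    rng = np.random.default_rng(seed)
    pos_folds = _stratified_folds(len(pos), folds, rng)
    neg_folds = _stratified_folds(len(neg), folds, rng)
    if any(f.size == 0 for f in pos_folds + neg_folds):
        raise ValueError("a fold has an empty class; reduce the number of folds")
    results = []
    for kappa in kappa_grid:
        sens, leaves = [], []
        for f in range(folds):
            hop = set(pos_folds[f].tolist())
            hon = set(neg_folds[f].tolist())
            tr_pos = [p for i, p in enumerate(pos) if i not in hop]
            tr_neg = [q for i, q in enumerate(neg) if i not in hon]
            te_pos = [pos[i] for i in pos_folds[f]]
            te_neg = [neg[i] for i in neg_folds[f]]
            bg = train_background(tr_pos, tr_neg, order=bg_order, ess=base.ess)
            cfg = ZOOPSConfig(
                width=base.width, max_order=base.max_order, log2_kappa=kappa,
                ess=base.ess, restarts=base.restarts, max_iter=base.max_iter,
                tol=base.tol, strand_prob=base.strand_prob, em_score=base.em_score,
            )
            model, _ = fit_zoops_em(tr_pos, bg, cfg, seed=seed * 1000 + f)
            sens.append(
                sensitivity_at_specificity(
                    _score_values(model, bg, te_pos),
                    _score_values(model, bg, te_neg),
                    specificity,
                )
            )
            leaves.append(leaf_statistics(model.motif)[1])
        results.append(CVResult(kappa, sens, [float(x) for x in leaves]))
    best = max(results, key=lambda r: (r.mean_sensitivity, -r.mean_leaves))
    return results, best.log2_kappa


def cv_table(results: list[CVResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "log2_kappa": [r.log2_kappa for r in results],
            "mean_sens": [r.mean_sensitivity for r in results],
            "se": [r.se_sensitivity for r in results],
            "mean_leaves": [r.mean_leaves for r in results],
        }
    )
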
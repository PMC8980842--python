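"""Predictive evaluation of eigengenes and recovery scoring against ground truth.

The pre-therapy module eigengene is used as a classifier score for
subsequent anti-TNF response; the AUC is the Mann-Whitney probability that
a random nonresponder scores above a random responder (ties half-credited).
Recovery metrics compare detected modules, screened regulators and retained
targets with the planted truth of a synthetic dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .containers import SampleAnnotation
from .coexpression import EigengeneMatrix
from .simulate import GroundTruth

__all__ = [
    "ROCResult",
    "roc_auc",
    "eigengene_predictor",
    "RecoveryReport",
    "recovery_metrics",
    "EvaluationError",
]


class EvaluationError(ValueError):
    pass


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int
    positive_class: str = "1"
    # True when a higher score indicates the positive class (AUC > 0.5)
    higher_score_positive: bool = True

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores, labels, positive_class="1") -> ROCResult:
    """ROC curve and AUC via the Mann-Whitney identity (ties half-credited)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present")

    ranks = rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # threshold sweep over unique scores, descending; predict positive at score >= t
    uniq = np.unique(s)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    thresholds = [np.inf]
    for t in uniq:
        pred = s >= t
        tpr.append(float((pred & y).sum() / n_pos))
        fpr.append(float((pred & ~y).sum() / n_neg))
        thresholds.append(float(t))
    return ROCResult(
        auc=float(auc),
        fpr=np.array(fpr),
        tpr=np.array(tpr),
        thresholds=np.array(thresholds),
        n_pos=n_pos,
        n_neg=n_neg,
        positive_class=str(positive_class),
        higher_score_positive=bool(auc >= 0.5),
    )


def eigengene_predictor(
    eigengenes: EigengeneMatrix,
    annotation: SampleAnnotation,
    module: str,
    response_field: str = "response",
    positive_class: str = "nonresponder",
) -> ROCResult:
    """AUC of a module eigengene as predictor of therapy nonresponse.

    Only samples carrying a response label are scored; the positive class
    defaults to nonresponder (high inflammatory-module activity predicts
    failure of anti-TNF therapy).
    """
    if module not in eigengenes.modules:
        raise EvaluationError(f"module {module!r} not present")
    labels = annotation.table[response_field]
    labelled = labels.dropna().index
    labelled = [s for s in eigengenes.eigengenes.columns if s in set(labelled)]
    if not labelled:
        raise EvaluationError("no samples carry a response label")
    scores = eigengenes.eigengenes.loc[module, labelled]
    y = (labels[labelled] == positive_class).to_numpy()
    return roc_auc(scores.to_numpy(), y, positive_class=positive_class)


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted structure."""

    module_ari: float
    screen_sensitivity: float
    screen_specificity: float
    target_sensitivity: float
    target_precision: float
    regulator_ranks: dict[str, float]  # planted regulator -> 1-based rank (inf if absent)

    def to_dict(self) -> dict:
        return {
            "module_ari": self.module_ari,
            "screen_sensitivity": self.screen_sensitivity,
            "screen_specificity": self.screen_specificity,
            "target_sensitivity": self.target_sensitivity,
            "target_precision": self.target_precision,
            "regulator_ranks": self.regulator_ranks,
        }


def recovery_metrics(
    assignment_labels: pd.Series,
    screen: pd.DataFrame,
    integrated: pd.DataFrame,
    ranking: pd.DataFrame,
    truth: GroundTruth,
) -> RecoveryReport:
    """Score detected modules, the miR screen and the target filter vs truth.

    * module recovery: adjusted Rand index between detected labels and the
      planted gene->module map (over shared genes);
    * screen: sensitivity over planted (regulator, module) pairs, specificity
      over all other tested pairs;
    * targets: sensitivity and precision of retained (mir, gene) pairs vs
      planted true targets;
    * rank of each planted regulator in the target-count ranking.
    """
    shared = assignment_labels.index.intersection(truth.gene_modules.index)
    if len(shared) == 0:
        raise EvaluationError("no shared genes between assignment and truth")
    ari = float(
        adjusted_rand_score(truth.gene_modules[shared], assignment_labels[shared])
    )

    true_pairs = {(m, mod) for m, (mod, _c) in truth.regulators.items()}
    if screen.empty:
        sens = 0.0
        spec = 1.0
    else:
        tested = {(r.mir_id, r.module) for r in screen.itertuples()}
        selected = {(r.mir_id, r.module) for r in screen.itertuples() if r.selected}
        tp = len(true_pairs & selected)
        sens = tp / len(true_pairs & tested) if true_pairs & tested else 0.0
        null_pairs = tested - true_pairs
        spec = len(null_pairs - selected) / len(null_pairs) if null_pairs else 1.0

    true_targets = set(zip(truth.true_targets["mir_id"], truth.true_targets["gene_id"]))
    retained = (
        set(zip(integrated["mir_id"], integrated["gene_id"])) if not integrated.empty else set()
    )
    t_sens = len(retained & true_targets) / len(true_targets) if true_targets else 1.0
    t_prec = len(retained & true_targets) / len(retained) if retained else float("nan")

    ranks: dict[str, float] = {}
    rank_of = {m: i + 1 for i, m in enumerate(ranking["mir_id"])} if not ranking.empty else {}
    for mir_id in truth.regulators:
        ranks[mir_id] = float(rank_of.get(mir_id, np.inf))

    return RecoveryReport(ari, sens, spec, t_sens, t_prec, ranks)
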
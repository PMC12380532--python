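"""Evaluation metrics and reporting for ID regression and epitope classification.

Spearman correlation is the main regression criterion (immunodominance is a
ranking of residues); Pearson and R-squared are reported alongside. The
conventional binary epitope task is scored with AUC-ROC, AUC-PR and the
Matthews correlation coefficient (MCC). Per-protein reports macro-average
the metrics across test proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .curation import sequence_identity
from .graph_model import PredictionResult
from .io_formats import IDProfile


@dataclass
class MetricsReport:
    pearson: float = float("nan")
    spearman: float = float("nan")
    r2: float = float("nan")
    auc_roc: float = float("nan")
    auc_pr: float = float("nan")
    mcc: float = float("nan")
    n_residues: int = 0
    n_proteins: int = 0


def regression_metrics(pred: np.ndarray, target: np.ndarray) -> tuple[float, float, float]:
    """(Pearson, Spearman, R^2) of predictions against targets.

    Requires at least 3 residues and non-constant targets; a constant
    prediction has undefined correlations (NaN) but a well-defined R^2
    (0 for the mean predictor, negative for any other constant).
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.size < 3:
        raise ValueError("regression metrics need >= 3 paired values")
    if np.var(target) == 0.0:
        return float("nan"), float("nan"), float("nan")
    if np.var(pred) == 0.0:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(pred, target).statistic)
        spearman = float(stats.spearmanr(pred, target).statistic)
    ss_res = float(((target - pred) ** 2).sum())
    ss_tot = float(((target - target.mean()) ** 2).sum())
    return pearson, spearman, 1.0 - ss_res / ss_tot


def best_mcc_threshold(pred: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing MCC, searched over midpoints of sorted scores."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    uniq = np.unique(pred)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_m = candidates[0], -2.0
    for t in candidates:
        m = matthews_corrcoef(labels, pred > t)
        if m > best_m:
            best_m, best_t = m, float(t)
    return best_t


def classification_metrics(
    pred: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
) -> tuple[float, float, float]:
    """(AUC-ROC, AUC-PR, MCC) for binary epitope labels.

    Both classes must be present (otherwise all three are NaN). AUC-ROC uses
    the rank statistic with midranks for ties; AUC-PR is average precision.
    MCC is evaluated at ``threshold``; when None, the MCC-maximizing
    threshold on this data is used (report it alongside for honest use on a
    separate validation set).
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        return float("nan"), float("nan"), float("nan")
    auc_roc = float(roc_auc_score(labels, pred))
    auc_pr = float(average_precision_score(labels, pred))
    t = best_mcc_threshold(pred, labels) if threshold is None else threshold
    mcc = float(matthews_corrcoef(labels, pred > t))
    return auc_roc, auc_pr, mcc


def epitope_binarize(
    profile: IDProfile,
    external_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Binary epitope labels from an ID profile: epitope iff id_score > 0.

    Externally supplied labels (e.g. a benchmark's own annotation) take
    precedence over the profile-derived rule when provided.
    """
    if external_labels is not None:
        labels = np.asarray(external_labels, dtype=bool)
        if labels.size != len(profile):
            raise ValueError("external labels length != profile length")
        return labels
    return profile.scores > 0.0


def per_protein_report(
    results: list[PredictionResult],
    threshold: float | None = None,
) -> pd.DataFrame:
    """One metrics row per protein plus a macro-average row.

    Proteins failing a metric's preconditions (constant targets,
    single-class labels) keep their row with NaN entries and are excluded
    from the corresponding macro-average. Rows are ordered by antigen id;
    the macro-average row has antigen_id ``"macro_average"``.
    """
    rows = []
    for res in sorted(results, key=lambda r: r.antigen_id):
        if res.targets is None:
            raise ValueError(f"{res.antigen_id}: targets required for evaluation")
        pearson, spearman, r2 = regression_metrics(res.scores_raw, res.targets)
        labels = res.targets > 0.0
        auc_roc, auc_pr, mcc = classification_metrics(res.scores_raw, labels,
                                                      threshold=threshold)
        rows.append({
            "antigen_id": res.antigen_id, "n_residues": len(res),
            "pearson": pearson, "spearman": spearman, "r2": r2,
            "auc_roc": auc_roc, "auc_pr": auc_pr, "mcc": mcc,
        })
    df = pd.DataFrame(rows)
    macro = {"antigen_id": "macro_average", "n_residues": int(df["n_residues"].sum())}
    for col in ("pearson", "spearman", "r2", "auc_roc", "auc_pr", "mcc"):
        macro[col] = float(df[col].mean(skipna=True))
    return pd.concat([df, pd.DataFrame([macro])], ignore_index=True)


def remove_redundant(
    test_sequences: list[tuple[str, str]],
    train_sequences: list[tuple[str, str]],
    max_identity: float = 0.70,
) -> list[tuple[str, str]]:
    """Drop test sequences sharing > max_identity global-alignment identity
    with any training sequence (redundancy control for external benchmarks)."""
    kept = []
    for tid, tseq in test_sequences:
        if all(sequence_identity(tseq, s) <= max_identity for _, s in train_sequences):
            kept.append((tid, tseq))
    return kept
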
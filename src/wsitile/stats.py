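"""Statistical evaluation of slide-level classifiers.

One-vs-rest ROC/AUC per target label (adenocarcinoma and adenoma, with
non-neoplastic as the implicit rest class), percentile-bootstrap
confidence intervals over slide resamples, DeLong's test for two
correlated AUCs, per-slide one-vs-rest log loss with a paired two-sided
t-test, thresholded accuracy, and confusion matrices.

An *evaluation table* is a DataFrame with one row per slide: columns
``slide_id``, ``true_label`` and ``p_<label>`` for every label.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

from .labels import ADENOCARCINOMA, ADENOMA, LABELS

log = logging.getLogger(__name__)

#: labels reported in evaluation tables (one-vs-rest targets)
TARGET_LABELS = (ADENOCARCINOMA, ADENOMA)


def make_eval_table(predictions: list, true_labels: dict) -> pd.DataFrame:
    """Assemble an evaluation table from SlidePredictions."""
    rows = []
    for pred in predictions:
        row = {"slide_id": pred.slide_id, "true_label": true_labels[pred.slide_id]}
        row.update({f"p_{lab}": s for lab, s in zip(LABELS, pred.scores)})
        row["pred_label"] = pred.predicted_label
        rows.append(row)
    return pd.DataFrame(rows)


def _binary(table: pd.DataFrame, label: str) -> tuple[np.ndarray, np.ndarray]:
    y = (table["true_label"] == label).to_numpy(dtype=int)
    scores = table[f"p_{label}"].to_numpy(dtype=float)
    return scores, y


def roc_auc(scores, labels) -> float:
    """Mann–Whitney AUC (ties count one half)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_auc_ci(
    table: pd.DataFrame, label: str, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap interval over slide resamples.

    Resamples that lack one of the two classes are redrawn (and counted in
    a log message).
    """
    scores, y = _binary(table, label)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute an AUC")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if y[idx].min() != y[idx].max():
                break
            redraws += 1
        aucs[b] = roc_auc(scores[idx], y[idx])
    if redraws:
        log.info("bootstrap: redrew %d degenerate resamples", redraws)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong's test for two correlated ROC curves (midrank formulation).

    Returns (auc_a, auc_b, two-sided p). Paired scores over the same
    slides; the AUC difference is normalised by the variance derived from
    the structural components (placement values) of the Mann–Whitney
    statistic. If the difference and its variance are both zero, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pos = labels == labels.max()
    m, n = int(pos.sum()), int((~pos).sum())
    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, s in enumerate((scores_a, scores_b)):
        x, y = s[pos], s[~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[k] = auc
        v10[k] = (tz[:m] - tx) / n
        v01[k] = 1.0 - (tz[m:] - ty) / m
    # a class with a single slide carries no variance information
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


def one_vs_rest_log_loss(
    table: pd.DataFrame, label: str, clip_eps: float = 1e-15
) -> tuple[np.ndarray, float]:
    """Per-slide binary log loss for one target label, and its mean.

    loss_i = -[y_i ln p_i + (1 - y_i) ln(1 - p_i)] with y_i = 1 when the
    slide's true label is the target and p_i the slide's score for it,
    clipped to [eps, 1-eps].
    """
    scores, y = _binary(table, label)
    p = np.clip(scores, clip_eps, 1.0 - clip_eps)
    losses = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    return losses, float(losses.mean())


def bootstrap_log_loss_ci(
    table: pd.DataFrame, label: str, n_boot: int = 1000, seed: int = 0, clip_eps: float = 1e-15
) -> tuple[float, float]:
    losses, _ = one_vs_rest_log_loss(table, label, clip_eps)
    rng = np.random.default_rng(seed)
    n = len(losses)
    means = losses[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def paired_log_loss_test(losses_a, losses_b) -> float:
    """Paired two-sided t-test on per-slide loss differences.

    All-zero differences give p = 1 by convention (logged).
    """
    losses_a = np.asarray(losses_a, dtype=float)
    losses_b = np.asarray(losses_b, dtype=float)
    if losses_a.shape != losses_b.shape:
        raise ValueError("paired loss vectors must have equal length")
    if len(losses_a) < 2:
        raise ValueError("need at least 2 paired observations")
    diffs = losses_a - losses_b
    if np.all(diffs == 0):
        log.info("paired t-test: all differences zero; p = 1 by convention")
        return 1.0
    return float(sps.ttest_rel(losses_a, losses_b).pvalue)


def accuracy_at_threshold(
    table: pd.DataFrame, threshold: float = 0.5
) -> float:
    """Percent of slides called correctly at a probability threshold.

    A slide is called its argmax label when that label's score reaches the
    threshold, otherwise it falls back to non-neoplastic.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    score_cols = [f"p_{lab}" for lab in LABELS]
    scores = table[score_cols].to_numpy(dtype=float)
    calls = []
    for row in scores:
        best = row.argmax()  # first index wins ties = priority order
        calls.append(LABELS[best] if row[best] >= threshold else LABELS[-1])
    correct = (np.asarray(calls) == table["true_label"].to_numpy()).mean()
    return float(100.0 * correct)


def confusion_matrix(pred_labels, true_labels) -> np.ndarray:
    """3x3 counts, rows = true label, cols = predicted, order = LABELS."""
    return _sk_confusion(true_labels, pred_labels, labels=list(LABELS))


def optimal_threshold(scores, labels) -> float:
    """Youden-optimal operating threshold.

    Maximises J = TPR - FPR over thresholds placed midway between adjacent
    distinct scores; ties resolve to the midpoint of the tied candidates.
    With well-separated classes this lands mid-gap between the highest
    negative and lowest positive score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    pos = labels == labels.max()
    tpr = np.array([(scores[pos] > t).mean() for t in cands])
    fpr = np.array([(scores[~pos] > t).mean() for t in cands])
    j = tpr - fpr
    best = j == j.max()
    return float(cands[best].mean())


def roc_table(scores, labels) -> pd.DataFrame:
    """ROC curve as a (fpr, tpr, threshold) table."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_aggregators(
    table_mp: pd.DataFrame,
    table_rnn: pd.DataFrame,
    n_boot: int = 1000,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Full evaluation report comparing MP-aggr and RNN-aggr.

    Per target label: AUC with bootstrap CI and Youden-optimal threshold
    for each aggregator, the DeLong p for the AUC difference, mean log
    loss with bootstrap CI, and the paired t-test p on per-slide losses.
    Plus overall thresholded accuracy and confusion matrices.
    """
    if list(table_mp["slide_id"]) != list(table_rnn["slide_id"]):
        raise ValueError("MP and RNN tables must cover the same slides in order")
    report: dict = {"threshold": threshold, "n_slides": int(len(table_mp)), "labels": {}}
    for label in TARGET_LABELS:
        entry: dict = {}
        losses = {}
        for name, table in (("mp", table_mp), ("rnn", table_rnn)):
            scores, y = _binary(table, label)
            auc = roc_auc(scores, y)
            ci = bootstrap_auc_ci(table, label, n_boot=n_boot, seed=seed)
            ll_per_slide, ll = one_vs_rest_log_loss(table, label)
            ll_ci = bootstrap_log_loss_ci(table, label, n_boot=n_boot, seed=seed)
            losses[name] = ll_per_slide
            entry[name] = {
                "auc": auc,
                "auc_ci": ci,
                "log_loss": ll,
                "log_loss_ci": ll_ci,
                "optimal_threshold": optimal_threshold(scores, y),
            }
        _, _, delong_p = delong_test(
            table_mp[f"p_{label}"], table_rnn[f"p_{label}"], _binary(table_mp, label)[1]
        )
        entry["delong_p"] = delong_p
        entry["paired_log_loss_p"] = paired_log_loss_test(losses["mp"], losses["rnn"])
        report["labels"][label] = entry
    for name, table in (("mp", table_mp), ("rnn", table_rnn)):
        report[f"accuracy_{name}"] = accuracy_at_threshold(table, threshold)
        report[f"confusion_{name}"] = confusion_matrix(
            table["pred_label"], table["true_label"]
        ).tolist()
    return report


def format_report(report: dict) -> str:
    """Human-readable evaluation summary."""
    lines = [
        f"slides: {report['n_slides']}   accuracy@{report['threshold']}: "
        f"MP {report['accuracy_mp']:.1f}%  RNN {report['accuracy_rnn']:.1f}%",
        "",
        f"{'label':<16}{'aggr':<6}{'AUC':>7}{'95% CI':>17}{'logloss':>9}"
        f"{'95% CI':>17}{'opt thr':>9}",
    ]
    for label, entry in report["labels"].items():
        for name in ("mp", "rnn"):
            e = entry[name]
            lines.append(
                f"{label:<16}{name:<6}{e['auc']:>7.3f}"
                f"  ({e['auc_ci'][0]:.3f}-{e['auc_ci'][1]:.3f})"
                f"{e['log_loss']:>9.3f}"
                f"  ({e['log_loss_ci'][0]:.3f}-{e['log_loss_ci'][1]:.3f})"
                f"{e['optimal_threshold']:>9.3f}"
            )
        lines.append(
            f"{'':<16}DeLong p = {entry['delong_p']:.3g}; "
            f"paired log-loss t-test p = {entry['paired_log_loss_p']:.3g}"
        )
    return "\n".join(lines)


def save_report(report: dict, path: Path) -> None:
    path = Path(path)
    path.with_suffix(".json").write_text(json.dumps(report, indent=1))
    path.with_suffix(".txt").write_text(format_report(report) + "\n")
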
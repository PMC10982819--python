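"""Evaluation metrics for binary and ternary N staging.

Every metric follows a brute-force-verifiable definition: AUC is the
probability that a positive case outscores a negative one (ties half
credited), the ordinal concordance index extends the same pairwise credit
to three stages, DeLong's test compares correlated AUCs through placement
values, Cohen's kappa uses marginal-product expected agreement, and the
decision curve reports net benefit ``TP/n - (FP/n) * p_t / (1 - p_t)``.
Confidence intervals are percentile bootstrap (2000 stratified resamples,
seed-controlled) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import MetricError
from .staging import STAGE_ORDER, Stage

__all__ = [
    "roc_auc",
    "delong_test",
    "count_mae",
    "c_index_ordinal",
    "agreement_metrics",
    "decision_curve",
    "calibration_table",
    "sensitivity_specificity",
    "EvalReport",
    "evaluate_tables",
    "evaluate_cohort",
]

N_BOOT = 2000


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise MetricError("labels must be binary 0/1")
    return labels


def _auc_value(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie), via midranks."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _stratified_bootstrap_ci(stat, groups, n_boot, seed, alpha=0.05):
    """Percentile CI of ``stat(resampled index arrays per group)``."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = [g[rng.integers(0, g.size, g.size)] for g in groups]
        v = stat(np.concatenate(idx))
        if v is not None:
            vals.append(v)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def roc_auc(scores, labels, n_boot: int = N_BOOT, seed: int = 0):
    """AUC with a stratified percentile-bootstrap 95% CI.

    Returns ``(auc, (lo, hi))``. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels)
    if scores.shape != labels.shape:
        raise MetricError("roc_auc: scores and labels must have equal length")
    if labels.min() == labels.max():
        raise MetricError("roc_auc: AUC undefined with a single class")
    auc = float(_auc_value(scores, labels))
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]

    def stat(idx):
        return _auc_value(scores[idx], labels[idx])

    ci = _stratified_bootstrap_ci(stat, [pos_idx, neg_idx], n_boot, seed)
    return auc, ci


def _placements(scores, labels):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0), cmp.mean()


def delong_test(scores_a, scores_b, labels):
    """DeLong comparison of two correlated AUCs on paired cases.

    Returns ``(auc_a, auc_b, z, p_value)`` with a two-sided normal
    p-value. If the paired AUC difference has zero estimated variance
    (e.g. identical scores) the test is degenerate: ``z = 0, p = 1``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _as_binary(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise MetricError("delong_test: inputs must be paired (equal length)")
    if labels.min() == labels.max():
        raise MetricError("delong_test: undefined with a single class")
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0 or not np.isfinite(var):
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


def count_mae(k_hat, k_true, n_boot: int = N_BOOT, seed: int = 0):
    """Mean absolute error between predicted and true metastatic-node counts.

    Returns ``(mae, (lo, hi))`` with a percentile-bootstrap 95% CI.
    """
    k_hat = np.asarray(k_hat, dtype=float)
    k_true = np.asarray(k_true, dtype=float)
    if k_hat.shape != k_true.shape:
        raise MetricError("count_mae: inputs must have equal length")
    err = np.abs(k_hat - k_true)
    mae = float(err.mean())
    idx_all = np.arange(err.size)

    def stat(idx):
        return err[idx].mean()

    ci = _stratified_bootstrap_ci(stat, [idx_all], n_boot, seed)
    return mae, ci


def _stage_indices(stages) -> np.ndarray:
    out = []
    for s in stages:
        if isinstance(s, Stage):
            out.append(STAGE_ORDER[s])
        elif isinstance(s, str):
            out.append(STAGE_ORDER[Stage(s)])
        else:
            out.append(int(s))
    return np.asarray(out, dtype=int)


def _c_index_value(pred: np.ndarray, truth: np.ndarray) -> float:
    diff_t = truth[:, None] - truth[None, :]
    diff_p = pred[:, None] - pred[None, :]
    comparable = diff_t > 0  # ordered pairs (i truth-above j), each pair once
    n_pairs = int(comparable.sum())
    concordant = (diff_p > 0) & comparable
    tied = (diff_p == 0) & comparable
    return (concordant.sum() + 0.5 * tied.sum()) / n_pairs


def c_index_ordinal(pred, truth, n_boot: Optional[int] = None, seed: int = 0):
    """Concordance index for ordinal (ternary N) staging.

    Over all patient pairs with different true stages, a pair is
    concordant when the predicted ordinal score (typically the predicted
    metastatic count) orders the patients like the truth; tied predictions
    earn half credit. Returns the C index, or ``(c, (lo, hi))`` when
    ``n_boot`` is given.
    """
    pred = np.asarray(pred, dtype=float)
    truth = _stage_indices(truth)
    if pred.shape != truth.shape:
        raise MetricError("c_index_ordinal: inputs must have equal length")
    if np.unique(truth).size < 2:
        raise MetricError("c_index_ordinal: undefined with a single truth stage")
    c = float(_c_index_value(pred, truth))
    if n_boot is None:
        return c
    idx_all = np.arange(pred.size)

    def stat(idx):
        t = truth[idx]
        if np.unique(t).size < 2:
            return None
        return _c_index_value(pred[idx], t)

    ci = _stratified_bootstrap_ci(stat, [idx_all], n_boot, seed)
    return c, ci


def agreement_metrics(stage_pred, stage_true):
    """Confusion matrix (rows = truth), Cohen's kappa, per-class/macro F1.

    Returns a dict with keys ``confusion_matrix`` (3x3, truth N0/N1/N2 in
    rows), ``kappa``, ``f1_per_class``, ``f1_macro`` and ``accuracy``.
    Empty classes use the zero convention for F1.
    """
    pred = _stage_indices(stage_pred)
    true = _stage_indices(stage_true)
    if pred.shape != true.shape or pred.size == 0:
        raise MetricError("agreement_metrics: inputs must be equal-length, non-empty")
    k = 3
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (true, pred), 1)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / (n * n)
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    f1 = []
    for c in range(k):
        tp = cm[c, c]
        prec_den = cm[:, c].sum()
        rec_den = cm[c, :].sum()
        if tp == 0:
            f1.append(0.0)
        else:
            prec = tp / prec_den
            rec = tp / rec_den
            f1.append(2 * prec * rec / (prec + rec))
    return {
        "confusion_matrix": cm,
        "kappa": float(kappa),
        "f1_per_class": {"N0": f1[0], "N1": f1[1], "N2": f1[2]},
        "f1_macro": float(np.mean(f1)),
        "accuracy": float(p_o),
    }


def sensitivity_specificity(scores, labels, tau: float):
    """Sensitivity and specificity of ``score >= tau`` against binary truth."""
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels)
    pred = scores >= tau
    pos = labels == 1
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise MetricError("sensitivity_specificity: both classes required")
    sens = float((pred & pos).sum() / pos.sum())
    spec = float((~pred & ~pos).sum() / (~pos).sum())
    return sens, spec


def decision_curve(probs, labels, thresholds) -> pd.DataFrame:
    """Decision-curve analysis table.

    At threshold ``p_t`` the model's net benefit is
    ``TP/n - (FP/n) * p_t / (1 - p_t)`` with cases called positive when
    ``prob >= p_t``; treat-all is ``pi - (1 - pi) * p_t / (1 - p_t)`` with
    prevalence ``pi``; treat-none is identically zero. Thresholds equal to
    0 or 1 are excluded with a warning.
    """
    import warnings

    probs = np.asarray(probs, dtype=float)
    labels = _as_binary(labels)
    if probs.shape != labels.shape:
        raise MetricError("decision_curve: inputs must have equal length")
    thresholds = np.asarray(thresholds, dtype=float)
    keep = (thresholds > 0) & (thresholds < 1)
    if not keep.all():
        warnings.warn(
            "decision_curve: thresholds in {0, 1} are undefined and were dropped",
            stacklevel=2,
        )
        thresholds = thresholds[keep]
    n = labels.size
    pi = labels.mean()
    rows = []
    for p_t in thresholds:
        called = probs >= p_t
        tp = float((called & (labels == 1)).sum())
        fp = float((called & (labels == 0)).sum())
        odds = p_t / (1.0 - p_t)
        rows.append(
            {
                "threshold": p_t,
                "net_benefit_model": tp / n - (fp / n) * odds,
                "net_benefit_all": pi - (1.0 - pi) * odds,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def calibration_table(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability table: mean predicted vs observed rate per bin.

    Empty bins are emitted with ``n = 0`` and NaN summaries so the table
    always partitions [0, 1] into ``n_bins`` rows.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _as_binary(labels)
    if probs.shape != labels.shape:
        raise MetricError("calibration_table: inputs must have equal length")
    if n_bins < 2:
        raise MetricError(f"calibration_table: n_bins must be >= 2, got {n_bins}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        cnt = int(sel.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_predicted": float(probs[sel].mean()) if cnt else float("nan"),
                "observed_rate": float(labels[sel].mean()) if cnt else float("nan"),
                "n": cnt,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Patient-level evaluation of a fitted model on a test cohort."""

    n_patients: int
    auc: float
    auc_ci: tuple
    sensitivity: float
    specificity: float
    tau: float
    mae: float
    mae_ci: tuple
    c_index: float
    c_index_ci: tuple
    confusion_matrix: np.ndarray
    kappa: float
    f1_per_class: dict
    f1_macro: float
    accuracy: float
    calibration: pd.DataFrame = field(repr=False)
    decision: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tau": self.tau,
            "mae": self.mae,
            "mae_ci": list(self.mae_ci),
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "kappa": self.kappa,
            "f1_per_class": self.f1_per_class,
            "f1_macro": self.f1_macro,
            "accuracy": self.accuracy,
            "calibration": self.calibration.to_dict(orient="records"),
            "decision": self.decision.to_dict(orient="records"),
        }


def evaluate_tables(
    scores,
    k_hat,
    stage_pred,
    y,
    k_true,
    stage_true,
    tau: float,
    seed: int = 0,
    n_boot: int = N_BOOT,
) -> EvalReport:
    """Assemble the full report from prediction and truth columns.

    This is the CSV-facing entry point: the CLI ``evaluate`` subcommand
    joins a predictions table with a cohort manifest and calls this.
    """
    scores = np.asarray(scores, dtype=float)
    k_hat = np.asarray(k_hat, dtype=float)
    y = _as_binary(y)
    k_true = np.asarray(k_true, dtype=float)
    auc, auc_ci = roc_auc(scores, y, n_boot=n_boot, seed=seed)
    sens, spec = sensitivity_specificity(scores, y, tau)
    mae, mae_ci = count_mae(k_hat, k_true, n_boot=n_boot, seed=seed)
    c, c_ci = c_index_ordinal(k_hat, stage_true, n_boot=n_boot, seed=seed)
    agree = agreement_metrics(stage_pred, stage_true)
    cal = calibration_table(scores, y, n_bins=10)
    dca = decision_curve(scores, y, np.arange(0.05, 0.96, 0.05))
    return EvalReport(
        n_patients=int(scores.size),
        auc=auc,
        auc_ci=auc_ci,
        sensitivity=sens,
        specificity=spec,
        tau=tau,
        mae=mae,
        mae_ci=mae_ci,
        c_index=c,
        c_index_ci=c_ci,
        confusion_matrix=agree["confusion_matrix"],
        kappa=agree["kappa"],
        f1_per_class=agree["f1_per_class"],
        f1_macro=agree["f1_macro"],
        accuracy=agree["accuracy"],
        calibration=cal,
        decision=dca,
    )


def evaluate_cohort(model, bags, seed: int = 0, n_boot: int = N_BOOT) -> EvalReport:
    """Run the full metric suite for a fitted model on held-out bags.

    The patient score is ``p_max``; sensitivity/specificity use the
    training-derived threshold ``model.tau`` (never re-optimised here);
    the ordinal score for the C index is the predicted metastatic count.
    """
    preds = [model.predict(bag) for bag in bags]
    return evaluate_tables(
        scores=[p.patient_score for p in preds],
        k_hat=[p.k_hat for p in preds],
        stage_pred=[p.stage_pred for p in preds],
        y=[bag.y for bag in bags],
        k_true=[bag.n_metastatic for bag in bags],
        stage_true=[bag.stage_true for bag in bags],
        tau=model.tau,
        seed=seed,
        n_boot=n_boot,
    )
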
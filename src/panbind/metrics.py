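"""Evaluation metrics: ROC AUC and Pearson correlation.

Peptides are classified as binders at a 500 nM affinity threshold.  AUC
is computed as the normalized Mann-Whitney U statistic with ties counted
as one half; PCC is the standard product-moment correlation.  Per-allele
evaluation macro-averages over alleles (each allele weighted equally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

BINDER_THRESHOLD_NM = 500.0


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (single class, zero variance)."""


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    ``labels`` are truthy for positives.  Tied scores count 1/2.  Raises
    :class:`UndefinedMetricError` when either class is empty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined with {n_pos} positives and {n_neg} negatives"
        )
    ranks = rankdata(scores)  # average ranks implement the 1/2 tie rule
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pcc(pred, meas) -> float:
    """Pearson product-moment correlation coefficient.

    Raises :class:`UndefinedMetricError` for fewer than two points or a
    zero-variance argument.
    """
    x = np.asarray(pred, dtype=float)
    y = np.asarray(meas, dtype=float)
    if x.size != y.size:
        raise ValueError("pred and meas must have equal length")
    if x.size < 2:
        raise UndefinedMetricError("PCC needs at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise UndefinedMetricError("PCC undefined for a constant input")
    return float((xc * yc).sum() / (sx * sy))


@dataclass(frozen=True)
class EvalResult:
    """Per-group evaluation summary."""

    auc: float | None
    pcc: float | None
    n: int
    n_binders: int


@dataclass(frozen=True)
class EvalSummary:
    per_allele: Dict[str, EvalResult]
    mean_auc: float | None  # unweighted mean over alleles with defined AUC
    mean_pcc: float | None
    excluded_from_auc: Tuple[str, ...]  # alleles with a single class


def evaluate_predictions(scores, records, threshold_nM: float = BINDER_THRESHOLD_NM) -> EvalResult:
    """Evaluate one group of predictions against measured affinities.

    ``scores`` are predictions on the transformed [0, 1] scale (higher =
    stronger binding); records provide measured affinity and target.
    AUC/PCC are None when undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.array([r.affinity_nM <= threshold_nM for r in records])
    targets = np.array([r.target for r in records])
    try:
        a = auc(scores, labels)
    except UndefinedMetricError:
        a = None
    try:
        p = pcc(scores, targets)
    except UndefinedMetricError:
        p = None
    return EvalResult(auc=a, pcc=p, n=len(records), n_binders=int(labels.sum()))


def evaluate_per_allele(
    predictions: Sequence,
    records: Sequence,
    threshold_nM: float = BINDER_THRESHOLD_NM,
) -> EvalSummary:
    """Per-allele AUC/PCC plus unweighted averages across alleles.

    ``predictions`` and ``records`` are aligned (prediction i is for
    record i); each prediction exposes ``.score``.  Alleles where AUC is
    undefined (all binders or none) are flagged and excluded from the
    averaged AUC, likewise for PCC.
    """
    if len(predictions) != len(records):
        raise ValueError("predictions and records must be aligned")
    by_allele: Dict[str, list] = {}
    for pred, rec in zip(predictions, records):
        if pred.peptide != rec.peptide or pred.allele != rec.allele:
            raise ValueError(
                f"misaligned prediction {pred.peptide}/{pred.allele} vs "
                f"record {rec.peptide}/{rec.allele}"
            )
        by_allele.setdefault(rec.allele, []).append((pred.score, rec))
    per_allele: Dict[str, EvalResult] = {}
    for allele in sorted(by_allele):
        pairs = by_allele[allele]
        per_allele[allele] = evaluate_predictions(
            [s for s, _ in pairs], [r for _, r in pairs], threshold_nM
        )
    aucs = [r.auc for r in per_allele.values() if r.auc is not None]
    pccs = [r.pcc for r in per_allele.values() if r.pcc is not None]
    excluded = tuple(a for a, r in per_allele.items() if r.auc is None)
    return EvalSummary(
        per_allele=per_allele,
        mean_auc=float(np.mean(aucs)) if aucs else None,
        mean_pcc=float(np.mean(pccs)) if pccs else None,
        excluded_from_auc=excluded,
    )
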
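"""Evaluation protocols: leave-one-out designs and the ligand benchmark.

Two leave-one-out (LOO) designs measure extrapolation to uncharacterized
alleles.  ``loo_allele`` drops every record of the target allele from
training and predicts them through the pseudo sequence alone.
``loo_peptide`` is stricter: every measurement of an evaluation peptide
against *any* allele is withheld, run as an inner 3-fold cross-validation
when the target allele has more than 200 data points (one full-exclusion
round otherwise).

The ligand benchmark scans each ligand's source protein with overlapping
windows of the ligand's length; only windows identical in sequence to the
annotated ligand count as positives (a deliberately stringent rule), and
performance is the per-ligand AUC, aggregated per ligand, per allele, and
per ligand-length bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from panbind.data_io import Allele, BindingRecord, LigandRecord
from panbind.metrics import (
    EvalResult,
    UndefinedMetricError,
    auc,
    evaluate_predictions,
)
from panbind.trainer import (
    Ensemble,
    TrainConfig,
    partition_data,
    train_networks,
)

logger = logging.getLogger(__name__)

#: above this many data points the peptide-exclusion LOO runs 3 inner folds
PEPTIDE_LOO_FOLD_THRESHOLD = 200
PEPTIDE_LOO_INNER_FOLDS = 3

DEFAULT_LENGTH_FILTER = (9, 24)


@dataclass(frozen=True)
class LOODesign:
    kind: str  # "allele_exclusion" or "peptide_exclusion"
    target_allele: str
    inner_folds: int = 1


@dataclass
class LOOResult:
    design: LOODesign
    eval: EvalResult
    predictions: list  # PredictionResult per evaluated record
    records: List[BindingRecord]


def loo_allele(
    records: Sequence[BindingRecord],
    allele_name: str,
    allele_table: Dict[str, Allele],
    cfg: TrainConfig,
) -> LOOResult:
    """Train without the target allele's data; evaluate on that data.

    The target's pseudo sequence is still available at prediction time —
    the pan-specific extrapolation path.
    """
    from panbind.predictor import predict

    eval_records = [r for r in records if r.allele == allele_name]
    if not eval_records:
        raise ValueError(f"no records for allele {allele_name}")
    train_records = [r for r in records if r.allele != allele_name]
    if not train_records:
        raise ValueError("nothing left to train on after excluding the target allele")
    nets = train_networks(train_records, allele_table, cfg, fold=0)
    ensemble = Ensemble(nets, cfg, allele_table, fold=None)
    preds = [predict(ensemble, r.peptide, r.allele) for r in eval_records]
    result = evaluate_predictions([p.score for p in preds], eval_records)
    design = LOODesign("allele_exclusion", allele_name)
    return LOOResult(design, result, preds, eval_records)


def loo_peptide(
    records: Sequence[BindingRecord],
    allele_name: str,
    allele_table: Dict[str, Allele],
    cfg: TrainConfig,
) -> LOOResult:
    """Exclude every measurement of each evaluation peptide from training.

    Evaluation partitions of the target allele's records come from the
    same shared-9-mer clustering used for cross-validation, seeded by the
    config's master seed.  The union of partitions is exactly the target
    allele's record set.
    """
    from panbind.predictor import predict

    target_records = [r for r in records if r.allele == allele_name]
    if not target_records:
        raise ValueError(f"no records for allele {allele_name}")
    if len(target_records) > PEPTIDE_LOO_FOLD_THRESHOLD:
        n_rounds = PEPTIDE_LOO_INNER_FOLDS
        labels = partition_data(target_records, n_rounds, seed=cfg.master_seed)
    else:
        n_rounds = 1
        labels = np.zeros(len(target_records), dtype=np.int64)

    preds_all, eval_all = [], []
    for f in range(n_rounds):
        eval_recs = [r for r, lab in zip(target_records, labels) if lab == f]
        excluded_peptides = {r.peptide for r in eval_recs}
        train_recs = [r for r in records if r.peptide not in excluded_peptides]
        if not train_recs:
            raise ValueError("nothing left to train on after peptide exclusion")
        nets = train_networks(train_recs, allele_table, cfg, fold=f)
        ensemble = Ensemble(nets, cfg, allele_table, fold=None)
        preds_all.extend(predict(ensemble, r.peptide, r.allele) for r in eval_recs)
        eval_all.extend(eval_recs)
    result = evaluate_predictions([p.score for p in preds_all], eval_all)
    design = LOODesign("peptide_exclusion", allele_name, inner_folds=n_rounds)
    return LOOResult(design, result, preds_all, eval_all)


# ---------------------------------------------------------------------------
# ligand / epitope benchmark


@dataclass(frozen=True)
class LigandAUC:
    protein_id: str
    ligand: str
    allele: str
    auc: float
    n_windows: int


@dataclass
class LigandBenchmarkResult:
    per_ligand: List[LigandAUC]
    mean_per_ligand: float | None  # mean over ligands
    mean_per_allele: float | None  # mean over alleles of within-allele means
    per_allele: Dict[str, float]
    per_length: Dict[int, float]  # ligand length -> mean AUC
    n_length_excluded: int
    n_skipped: int  # ligand not found in protein, or degenerate AUC


def _ensemble_scorer(ensemble: Ensemble) -> Callable[[str, str], float]:
    from panbind.predictor import predict

    return lambda peptide, allele: predict(ensemble, peptide, allele).score


def ligand_benchmark(
    proteins: Dict[str, str],
    ligands: Sequence[LigandRecord],
    model,
    length_filter: Tuple[int, int] | None = DEFAULT_LENGTH_FILTER,
) -> LigandBenchmarkResult:
    """Overlapping-window ligand identification benchmark.

    ``model`` is either an :class:`Ensemble` or a callable
    ``scorer(peptide, allele_name) -> float`` (higher = stronger).  For
    each (protein, ligand, allele) the protein is split into all windows
    of the ligand's length; windows whose sequence equals the ligand are
    positives, every other window is a negative; performance is the AUC.
    """
    scorer = model if callable(model) else _ensemble_scorer(model)
    per_ligand: List[LigandAUC] = []
    n_excluded = n_skipped = 0
    for lig in ligands:
        if length_filter is not None and not (
            length_filter[0] <= len(lig.ligand) <= length_filter[1]
        ):
            n_excluded += 1
            continue
        protein = proteins.get(lig.protein_id)
        if protein is None or lig.ligand not in protein:
            logger.warning(
                "ligand %s not found in protein %s; skipped", lig.ligand, lig.protein_id
            )
            n_skipped += 1
            continue
        llen = len(lig.ligand)
        windows = [protein[i : i + llen] for i in range(len(protein) - llen + 1)]
        labels = [w == lig.ligand for w in windows]
        scores = [scorer(w, lig.allele) for w in windows]
        try:
            value = auc(scores, labels)
        except UndefinedMetricError:
            logger.warning(
                "single-class window set for ligand %s in %s; skipped",
                lig.ligand, lig.protein_id,
            )
            n_skipped += 1
            continue
        per_ligand.append(LigandAUC(lig.protein_id, lig.ligand, lig.allele, value, len(windows)))

    by_allele: Dict[str, List[float]] = {}
    by_length: Dict[int, List[float]] = {}
    for la in per_ligand:
        by_allele.setdefault(la.allele, []).append(la.auc)
        by_length.setdefault(len(la.ligand), []).append(la.auc)
    per_allele = {a: float(np.mean(v)) for a, v in sorted(by_allele.items())}
    per_length = {l: float(np.mean(v)) for l, v in sorted(by_length.items())}
    return LigandBenchmarkResult(
        per_ligand=per_ligand,
        mean_per_ligand=float(np.mean([la.auc for la in per_ligand])) if per_ligand else None,
        mean_per_allele=float(np.mean(list(per_allele.values()))) if per_allele else None,
        per_allele=per_allele,
        per_length=per_length,
        n_length_excluded=n_excluded,
        n_skipped=n_skipped,
    )


def read_ligand_table(path) -> List[LigandRecord]:
    """Read a tab-separated (protein_id, ligand, allele) table."""
    ligands = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            pid, lig, allele = line.split("\t")
            ligands.append(LigandRecord(pid, lig.upper(), allele))
    return ligands
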
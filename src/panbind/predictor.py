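"""Ensemble prediction with majority-vote core assignment.

Every network in the ensemble reports its own best 9-mer core and the
score at that core.  The ensemble score is the arithmetic mean of the
per-network scores (averaged on the transformed [0, 1] scale, then
converted to nM); the reported core is the modal per-network offset,
ties broken by the higher mean score among the tied offsets, then by the
smaller offset.  Alleles never seen in training are handled through
their pseudo sequence alone — the pan-specific path.
"""

from __future__ import annotations

import difflib
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from panbind.data_io import Allele, CORE_LENGTH, target_to_affinity
from panbind.trainer import Ensemble, find_best_core


@dataclass(frozen=True)
class PredictionResult:
    """Ensemble output for one (peptide, allele) pair."""

    peptide: str
    allele: str
    score: float  # mean transformed-affinity prediction, in [0, 1]
    predicted_nM: float  # base ** (1 - score)
    core_offset: int  # 0-based
    core_seq: str


class UnknownAlleleError(KeyError):
    pass


def _resolve_allele(ensemble: Ensemble, allele) -> Allele:
    if isinstance(allele, Allele):
        return allele
    entry = ensemble.allele_table.get(allele)
    if entry is None:
        close = difflib.get_close_matches(allele, ensemble.allele_table, n=3, cutoff=0.0)
        raise UnknownAlleleError(
            f"allele {allele!r} has no pseudo sequence; nearest known alleles: "
            + ", ".join(close)
        )
    return entry


def predict(ensemble: Ensemble, peptide: str, allele) -> PredictionResult:
    """Predict one (peptide, allele) pair with the full ensemble.

    ``allele`` may be a name from the ensemble's pseudo table or an
    :class:`Allele` carrying its own pseudo sequence (pan-specific use).
    """
    if len(peptide) < CORE_LENGTH:
        raise ValueError(f"peptide {peptide!r} shorter than the {CORE_LENGTH}-mer core")
    entry = _resolve_allele(ensemble, allele)
    votes: dict[int, List[float]] = defaultdict(list)
    for net in ensemble.networks:
        offset, score = find_best_core(net, peptide, entry, net.scheme)
        votes[offset].append(score)
    n_nets = len(ensemble.networks)
    mean_score = sum(s for ss in votes.values() for s in ss) / n_nets
    max_votes = max(len(ss) for ss in votes.values())
    tied = [off for off, ss in votes.items() if len(ss) == max_votes]
    # ties: higher mean score among the voting networks, then smaller offset
    best_offset = min(
        tied, key=lambda off: (-(sum(votes[off]) / len(votes[off])), off)
    )
    return PredictionResult(
        peptide=peptide,
        allele=entry.name,
        score=mean_score,
        predicted_nM=target_to_affinity(mean_score, ensemble.config.base),
        core_offset=best_offset,
        core_seq=peptide[best_offset : best_offset + CORE_LENGTH],
    )


def predict_batch(
    ensemble: Ensemble, pairs: Iterable[Tuple[str, object]]
) -> List[PredictionResult]:
    """Order-preserving map of :func:`predict` over (peptide, allele) pairs."""
    return [predict(ensemble, peptide, allele) for peptide, allele in pairs]
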
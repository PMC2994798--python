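"""Readers and writers for binding data, pseudo sequences, FASTA and predictions.

All file formats are plain text.  Binding data is tab-separated with
columns ``peptide``, ``allele``, ``affinity_nM``.  Pseudo-sequence tables
are whitespace-separated two-column files (allele name, pseudo sequence).
Prediction files are tab-separated with a commented header; core offsets
are 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Base of the logarithmic affinity transform.  Affinities at or above
#: this value (in nM) map to a regression target of 0.
DEFAULT_BASE = 15000.0

CORE_LENGTH = 9


def affinity_to_target(affinity_nM: float, base: float = DEFAULT_BASE) -> float:
    """Map an IC50 affinity in nM to a regression target in [0, 1].

    target = 1 - log(affinity) / log(base), clamped to [0, 1].  Clamping
    keeps targets inside the output range of a logistic unit: affinities
    weaker than ``base`` score 0, affinities at or below 1 nM score 1.
    """
    if affinity_nM <= 0:
        raise ValueError(f"affinity must be positive, got {affinity_nM}")
    if base <= 1:
        raise ValueError(f"transform base must exceed 1, got {base}")
    t = 1.0 - math.log(affinity_nM) / math.log(base)
    return min(1.0, max(0.0, t))


def target_to_affinity(target: float, base: float = DEFAULT_BASE) -> float:
    """Inverse of :func:`affinity_to_target` on the unclamped range."""
    return base ** (1.0 - target)


@dataclass(frozen=True)
class BindingRecord:
    """One peptide/allele/affinity measurement with its regression target."""

    peptide: str
    allele: str
    affinity_nM: float
    target: float


@dataclass(frozen=True)
class Allele:
    """An allele name plus its MHC pseudo sequence (the pan-specific input)."""

    name: str
    pseudo: str


@dataclass(frozen=True)
class LigandRecord:
    """A naturally presented ligand / T-cell epitope with its source protein."""

    protein_id: str
    ligand: str
    allele: str


class BindingTable(List[BindingRecord]):
    """A list of binding records that remembers what was rejected at load."""

    def __init__(self, records: Iterable[BindingRecord] = (), rejections=None):
        super().__init__(records)
        #: list of (row number, reason) pairs, 1-based row numbers
        self.rejections: List[Tuple[int, str]] = list(rejections or [])

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _validate_peptide(peptide: str) -> str | None:
    """Return a rejection reason, or None if the peptide is acceptable."""
    if len(peptide) < CORE_LENGTH:
        return f"peptide shorter than {CORE_LENGTH} residues"
    bad = set(peptide) - _AA_SET
    if bad:
        return f"illegal residue(s) {''.join(sorted(bad))}"
    return None


def read_binding_data(path, base: float = DEFAULT_BASE) -> BindingTable:
    """Read tab-separated binding data (peptide, allele, affinity_nM).

    Targets are computed with :func:`affinity_to_target`.  Rows with short
    peptides, non-standard residues, or non-positive/unparseable affinities
    are rejected; rejections are counted on the returned table and logged
    with their 1-based row numbers.  Raises if the file is missing, empty,
    or every row is rejected.
    """
    path = Path(path)
    if base <= 1:
        raise ValueError(f"transform base must exceed 1, got {base}")
    records: List[BindingRecord] = []
    rejections: List[Tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:3] == ["peptide", "allele", "affinity_nM"]:
                continue  # optional header
            if len(fields) < 3:
                rejections.append((lineno, "expected 3 tab-separated columns"))
                continue
            peptide, allele = fields[0].strip().upper(), fields[1].strip()
            reason = _validate_peptide(peptide)
            if reason is None and not allele:
                reason = "empty allele name"
            if reason is None:
                try:
                    affinity = float(fields[2])
                except ValueError:
                    reason = f"unparseable affinity {fields[2]!r}"
                else:
                    if not (affinity > 0 and math.isfinite(affinity)):
                        reason = f"non-positive affinity {affinity}"
            if reason is not None:
                rejections.append((lineno, reason))
                continue
            records.append(
                BindingRecord(peptide, allele, affinity, affinity_to_target(affinity, base))
            )
    for lineno, reason in rejections:
        logger.warning("%s row %d rejected: %s", path, lineno, reason)
    if not records:
        raise ValueError(f"{path}: no valid binding records")
    return BindingTable(records, rejections)


def read_pseudosequences(path) -> Dict[str, Allele]:
    """Read a two-column (allele name, pseudo sequence) table.

    All pseudo sequences must share one length; an inconsistent entry is an
    error naming the offending allele.  Duplicate names: last wins, with a
    warning.
    """
    path = Path(path)
    table: Dict[str, Allele] = {}
    length: int | None = None
    first_allele = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or line.lstrip().startswith("#"):
                continue
            if len(fields) != 2:
                raise ValueError(f"{path} line {lineno}: expected 2 columns, got {len(fields)}")
            name, pseudo = fields[0], fields[1].upper()
            if length is None:
                length, first_allele = len(pseudo), name
            elif len(pseudo) != length:
                raise ValueError(
                    f"{path}: pseudo sequence of {name} has length {len(pseudo)}, "
                    f"but {first_allele} has length {length}"
                )
            if name in table:
                logger.warning("%s line %d: duplicate allele %s, keeping last", path, lineno, name)
            table[name] = Allele(name, pseudo)
    if not table:
        raise ValueError(f"{path}: empty pseudo-sequence table")
    return table


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into {id: uppercased sequence}.

    Ids are truncated at the first whitespace.  Duplicate ids are an error.
    Sequences containing non-standard residues (e.g. X) are accepted and
    flagged with a warning; downstream encoding maps them to zero vectors.
    """
    path = Path(path)
    proteins: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteins:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id}")
        seq = str(rec.seq).upper()
        nonstd = set(seq) - _AA_SET
        if nonstd:
            logger.warning(
                "%s: sequence %s contains non-standard residues %s",
                path, rec.id, "".join(sorted(nonstd)),
            )
        proteins[rec.id] = seq
    if not proteins:
        raise ValueError(f"{path}: no FASTA records")
    return proteins


_PRED_HEADER = [
    "# panbind predictions; core_offset is 0-based",
    "peptide\tallele\tscore\tpredicted_nM\tcore_offset\tcore_sequence",
]


def write_predictions(path, results) -> None:
    """Write prediction results as TSV (fixed decimal precision).

    Columns: peptide, allele, score, predicted_nM, core_offset,
    core_sequence.  Round-trips bit-exactly through
    :func:`read_predictions` at the written precision.
    """
    with open(path, "w") as fh:
        for line in _PRED_HEADER:
            fh.write(line + "\n")
        for r in results:
            fh.write(
                f"{r.peptide}\t{r.allele}\t{r.score:.6f}\t{r.predicted_nM:.4f}"
                f"\t{r.core_offset}\t{r.core_seq}\n"
            )


def read_predictions(path):
    """Read a prediction TSV written by :func:`write_predictions`."""
    from panbind.predictor import PredictionResult

    results = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("peptide\t"):
                continue
            pep, allele, score, nm, off, core = line.split("\t")
            results.append(
                PredictionResult(pep, allele, float(score), float(nm), int(off), core)
            )
    return results
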
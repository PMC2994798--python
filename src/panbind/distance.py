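"""Allele distance from pseudo-sequence similarity.

d(A, B) = 1 - s(A, B) / sqrt(s(A, A) * s(B, B)), where s is the summed
BLOSUM50 score over the aligned pseudo-sequence positions (pseudo
sequences are pre-aligned by construction, so no gaps).  Identical
sequences have distance 0; very dissimilar pairs may exceed 1 under
BLOSUM50 cross-scores, and are reported as-is.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Tuple

import numpy as np

from panbind.data_io import Allele
from panbind.encoding import load_blosum50


def similarity(a: Allele, b: Allele, matrix=None) -> float:
    """Summed substitution score between two equal-length pseudo sequences."""
    if len(a.pseudo) != len(b.pseudo):
        raise ValueError(
            f"pseudo length mismatch: {a.name} ({len(a.pseudo)}) vs {b.name} ({len(b.pseudo)})"
        )
    if matrix is None:
        matrix = load_blosum50()
    return float(sum(matrix[x, y] for x, y in zip(a.pseudo, b.pseudo)))


def nn_distance(a: Allele, b: Allele, matrix=None) -> float:
    """1 - s(a,b)/sqrt(s(a,a)*s(b,b)); 0 for identical pseudo sequences."""
    if matrix is None:
        matrix = load_blosum50()
    saa = similarity(a, a, matrix)
    sbb = similarity(b, b, matrix)
    if saa <= 0 or sbb <= 0:
        raise ValueError("non-positive self-similarity; cannot normalize")
    return 1.0 - similarity(a, b, matrix) / math.sqrt(saa * sbb)


def nearest_neighbor(query: Allele, training: Iterable[Allele], matrix=None) -> Tuple[str, float]:
    """Closest training allele by pseudo distance; ties go to the lexically
    smallest name.  The query itself is skipped if present in ``training``."""
    if matrix is None:
        matrix = load_blosum50()
    candidates = [t for t in training if t.name != query.name]
    if not candidates:
        raise ValueError("training set is empty (or contains only the query)")
    best = min(candidates, key=lambda t: (nn_distance(query, t, matrix), t.name))
    return best.name, nn_distance(query, best, matrix)


def distance_matrix(alleles: Iterable[Allele], matrix=None) -> Tuple[list, np.ndarray]:
    """All pairwise distances; returns (names, symmetric matrix)."""
    alleles = list(alleles)
    if matrix is None:
        matrix = load_blosum50()
    n = len(alleles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = nn_distance(alleles[i], alleles[j], matrix)
    return [a.name for a in alleles], out
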
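"""Residue and example encoding for the network input.

One training/prediction example is a (peptide, core offset, allele)
triple.  It is encoded as the concatenation, in this frozen order, of

  1. the 9 core residues, 20 values each               (180)
  2. the allele pseudo-sequence residues, 20 each      (20 * pseudo_len)
  3. the N-terminal flank (PFR) summary                (20)
  4. the C-terminal flank (PFR) summary                (20)
  5. the peptide-length feature pair                   (2)
  6. the N-flank length pair, the C-flank length pair  (4)

which gives 20*(9 + pseudo_len) + 44 values: 646 at the default pseudo
length of 21.  A PFR summary is the arithmetic mean of the per-residue
encodings of up to ``pfr_cap`` residues adjacent to the core (empty flank
-> zero vector).  Scalar counts enter as complementary logistic pairs so
each contributes two bounded, monotone inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from panbind.data_io import AMINO_ACIDS, Allele, CORE_LENGTH

#: residue index used by every encoding scheme
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA = len(AMINO_ACIDS)

#: residues accepted in inputs but encoded as the zero vector
WILDCARDS = frozenset("XBJOUZ*")


def load_blosum50():
    """The packaged BLOSUM50 matrix (NCBI text format, parsed by biopython)."""
    ref = resources.files("panbind").joinpath("data/BLOSUM50.txt")
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return substitution_matrices.read(fh)


@dataclass(frozen=True)
class EncodingScheme:
    """How a single residue becomes 20 input values.

    kind ``sparse``: ``sparse_hi`` at the residue's own index and
    ``sparse_lo`` elsewhere.  kind ``blosum``: the residue's BLOSUM50 row
    divided by ``blosum_scale``.  Wildcard residues map to zeros either way.
    """

    kind: str  # "sparse" or "blosum"
    sparse_hi: float = 0.9
    sparse_lo: float = 0.05
    blosum_scale: float = 5.0

    def __post_init__(self):
        if self.kind not in ("sparse", "blosum"):
            raise ValueError(f"unknown encoding kind {self.kind!r}")

    def residue_table(self) -> np.ndarray:
        """(20, 20) array: row i encodes amino acid AMINO_ACIDS[i]."""
        return _residue_table(self)


@lru_cache(maxsize=None)
def _residue_table(scheme: EncodingScheme) -> np.ndarray:
    if scheme.kind == "sparse":
        table = np.full((N_AA, N_AA), scheme.sparse_lo)
        np.fill_diagonal(table, scheme.sparse_hi)
    else:
        mat = load_blosum50()
        table = np.empty((N_AA, N_AA))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                table[i, j] = mat[a, b] / scheme.blosum_scale
    table.setflags(write=False)
    return table


SCHEMES = {"sparse": EncodingScheme("sparse"), "blosum": EncodingScheme("blosum")}


def encode_residue(aa: str, scheme: EncodingScheme) -> np.ndarray:
    """Encode one residue as 20 values; wildcards give the zero vector."""
    idx = AA_INDEX.get(aa)
    if idx is None:
        if aa in WILDCARDS:
            return np.zeros(N_AA)
        raise ValueError(f"unknown residue {aa!r}")
    return scheme.residue_table()[idx].copy()


def encode_scalar_pair(x: float, half_point: float, slope: float) -> np.ndarray:
    """A nonnegative count as a complementary logistic pair.

    Returns (sigma((x - half_point)/slope), 1 - sigma(...)); strictly
    monotone in x, both components in (0, 1), (0.5, 0.5) at the half point.
    """
    s = 1.0 / (1.0 + math.exp(-(x - half_point) / slope))
    return np.array([s, 1.0 - s])


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the non-core feature blocks."""

    pfr_cap: int = 3
    pep_len_half: float = 15.0
    pep_len_slope: float = 2.0
    pfr_len_half: float = 2.0
    pfr_len_slope: float = 1.0


DEFAULT_FEATURES = FeatureConfig()


def input_length(pseudo_len: int, core_len: int = CORE_LENGTH) -> int:
    """Total encoded length: 20*(core_len + pseudo_len) + 2*20 + 2 + 4."""
    return N_AA * (core_len + pseudo_len) + 2 * N_AA + 2 + 4


def _encode_string(s: str, table: np.ndarray, out: np.ndarray) -> None:
    """Encode each residue of ``s`` into consecutive 20-wide slots of ``out``."""
    for i, aa in enumerate(s):
        idx = AA_INDEX.get(aa)
        if idx is not None:
            out[i * N_AA : (i + 1) * N_AA] = table[idx]
        elif aa not in WILDCARDS:
            raise ValueError(f"unknown residue {aa!r}")
        # wildcard: leave zeros


def _flank_summary(flank: str, table: np.ndarray) -> np.ndarray:
    """Mean residue encoding of a flank (already capped); empty -> zeros."""
    if not flank:
        return np.zeros(N_AA)
    acc = np.zeros(N_AA)
    for aa in flank:
        idx = AA_INDEX.get(aa)
        if idx is not None:
            acc += table[idx]
        elif aa not in WILDCARDS:
            raise ValueError(f"unknown residue {aa!r}")
    return acc / len(flank)


def encode_example(
    peptide: str,
    offset: int,
    allele: Allele,
    scheme: EncodingScheme,
    features: FeatureConfig = DEFAULT_FEATURES,
) -> np.ndarray:
    """Encode (peptide, 0-based core offset, allele) as the network input.

    Block layout is documented in the module docstring.  Raises if the
    offset does not leave a full core inside the peptide.
    """
    if not 0 <= offset <= len(peptide) - CORE_LENGTH:
        raise ValueError(
            f"core offset {offset} out of range for peptide of length {len(peptide)}"
        )
    table = scheme.residue_table()
    pseudo = allele.pseudo
    n = input_length(len(pseudo))
    out = np.zeros(n)

    core = peptide[offset : offset + CORE_LENGTH]
    _encode_string(core, table, out[: CORE_LENGTH * N_AA])
    pos = CORE_LENGTH * N_AA
    _encode_string(pseudo, table, out[pos : pos + len(pseudo) * N_AA])
    pos += len(pseudo) * N_AA

    n_flank_full = peptide[:offset]
    c_flank_full = peptide[offset + CORE_LENGTH :]
    cap = features.pfr_cap
    n_flank = n_flank_full[-cap:] if n_flank_full else ""
    c_flank = c_flank_full[:cap]
    out[pos : pos + N_AA] = _flank_summary(n_flank, table)
    pos += N_AA
    out[pos : pos + N_AA] = _flank_summary(c_flank, table)
    pos += N_AA

    out[pos : pos + 2] = encode_scalar_pair(
        len(peptide), features.pep_len_half, features.pep_len_slope
    )
    pos += 2
    out[pos : pos + 2] = encode_scalar_pair(
        len(n_flank_full), features.pfr_len_half, features.pfr_len_slope
    )
    pos += 2
    out[pos : pos + 2] = encode_scalar_pair(
        len(c_flank_full), features.pfr_len_half, features.pfr_len_slope
    )
    return out


def encode_all_offsets(
    peptide: str,
    allele: Allele,
    scheme: EncodingScheme,
    features: FeatureConfig = DEFAULT_FEATURES,
) -> np.ndarray:
    """Stack encode_example over every candidate core offset.

    Returns an array of shape (len(peptide) - 8, input_length).
    """
    n_off = len(peptide) - CORE_LENGTH + 1
    if n_off < 1:
        raise ValueError(f"peptide {peptide!r} shorter than the {CORE_LENGTH}-mer core")
    return np.stack(
        [encode_example(peptide, k, allele, scheme, features) for k in range(n_off)]
    )
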
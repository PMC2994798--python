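"""Synthetic multi-allele binding data with planted 9-mer motifs.

Alleles are generated along a random tree: each child mutates its
parent's pseudo sequence position-wise.  Every allele's 9x20 position
score matrix (PSSM) is a fixed random linear map of its one-hot pseudo
sequence, so pseudo-sequence similarity and motif similarity are coupled
by construction — the property a pan-specific predictor exploits.  Rows
of the PSSM are standardized (zero mean, unit variance across residues),
log-odds style.

A peptide's true core is the PSSM-argmax offset; its latent target is a
logistic squash of the best core score plus Gaussian noise on the
transformed [0, 1] scale, and the affinity is the inverse log transform
of that target.  Ground-truth core offsets are carried on every record.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from panbind.data_io import (
    AMINO_ACIDS,
    Allele,
    BindingRecord,
    CORE_LENGTH,
    DEFAULT_BASE,
    LigandRecord,
    affinity_to_target,
    target_to_affinity,
)

N_AA = len(AMINO_ACIDS)
PSEUDO_LENGTH = 21

#: latent-target squash: target_raw = logistic((best_score - CENTER) / SCALE)
SCORE_CENTER = 5.6
SCORE_SCALE = 2.4

#: per-position motif strength; strong anchors at core positions 1, 4, 6, 9
#: give planted cores a clear margin over competing offsets, as in real
#: MHC-II binding motifs
ANCHOR_WEIGHTS = np.array([2.4, 0.4, 0.4, 1.8, 0.4, 1.8, 0.4, 0.4, 2.4])


@dataclass(frozen=True)
class SyntheticAllele:
    """A generated allele: pseudo sequence, planted motif, and parentage."""

    name: str
    pseudo: str
    pssm: np.ndarray  # (9, 20), rows standardized
    lineage: str | None  # parent allele name, None at the root

    def as_allele(self) -> Allele:
        return Allele(self.name, self.pseudo)


@dataclass(frozen=True)
class SyntheticRecord(BindingRecord):
    """A binding record that remembers its planted core offset."""

    true_core_offset: int = 0


def _standardize_rows(pssm: np.ndarray) -> np.ndarray:
    mu = pssm.mean(axis=1, keepdims=True)
    sd = pssm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (pssm - mu) / sd * ANCHOR_WEIGHTS[:, None]


def _pssm_from_pseudo(pseudo: str, gmap: np.ndarray, jitter: np.ndarray | None) -> np.ndarray:
    onehot = np.zeros((PSEUDO_LENGTH, N_AA))
    for p, aa in enumerate(pseudo):
        onehot[p, AMINO_ACIDS.index(aa)] = 1.0
    pssm = np.einsum("iapq,pq->ia", gmap, onehot)
    if jitter is not None:
        pssm = pssm + jitter
    return _standardize_rows(pssm)


def generate_alleles(
    n: int,
    seed: int = 0,
    mutation_rate: float = 0.15,
    jitter_sd: float = 0.0,
) -> List[SyntheticAllele]:
    """Generate ``n`` alleles along a random tree, deterministic given seed.

    Each non-root allele picks a random earlier allele as parent and
    mutates each pseudo position independently with ``mutation_rate``.
    PSSMs derive from pseudo sequences through one fixed random linear
    map, so motif distance tracks pseudo distance; ``jitter_sd`` adds
    optional allele-private motif noise (0 keeps the coupling exact:
    mutation_rate 0 then yields identical alleles).
    """
    if n < 1:
        raise ValueError("need at least one allele")
    rng = np.random.default_rng(seed)
    # fixed map from one-hot pseudo to PSSM entries; variance chosen so
    # summing 21 positions gives O(1) entries before standardization
    gmap = rng.normal(0.0, 1.0 / np.sqrt(PSEUDO_LENGTH), size=(CORE_LENGTH, N_AA, PSEUDO_LENGTH, N_AA))
    aa = np.array(list(AMINO_ACIDS))
    root_pseudo = "".join(rng.choice(aa, size=PSEUDO_LENGTH))
    alleles: List[SyntheticAllele] = []

    def make(name, pseudo, lineage):
        jitter = rng.normal(0.0, jitter_sd, size=(CORE_LENGTH, N_AA)) if jitter_sd > 0 else None
        return SyntheticAllele(name, pseudo, _pssm_from_pseudo(pseudo, gmap, jitter), lineage)

    alleles.append(make("SYN-00", root_pseudo, None))
    for i in range(1, n):
        parent = alleles[int(rng.integers(0, i))]
        # heterogeneous branch lengths spread the nearest-neighbor distances
        branch_rate = mutation_rate * rng.uniform(0.4, 2.0)
        pseudo = list(parent.pseudo)
        for p in range(PSEUDO_LENGTH):
            if rng.random() < branch_rate:
                choices = [c for c in AMINO_ACIDS if c != pseudo[p]]
                pseudo[p] = choices[int(rng.integers(0, len(choices)))]
        alleles.append(make(f"SYN-{i:02d}", "".join(pseudo), parent.name))
    return alleles


def pssm_score(pssm: np.ndarray, core: str) -> float:
    """Summed per-position score of one 9-mer core."""
    return float(sum(pssm[i, AMINO_ACIDS.index(aa)] for i, aa in enumerate(core)))


def best_core(pssm: np.ndarray, peptide: str) -> Tuple[int, float]:
    """PSSM-argmax core offset (ties to the smallest offset) and its score."""
    k, score, _ = _best_core_margin(pssm, peptide)
    return k, score


def _best_core_margin(pssm: np.ndarray, peptide: str) -> Tuple[int, float, float]:
    """(argmax offset, best score, margin over the runner-up offset)."""
    n_off = len(peptide) - CORE_LENGTH + 1
    if n_off < 1:
        raise ValueError("peptide shorter than the core")
    scores = [pssm_score(pssm, peptide[k : k + CORE_LENGTH]) for k in range(n_off)]
    k = int(np.argmax(scores))
    if n_off == 1:
        return k, scores[k], np.inf
    runner_up = max(s for j, s in enumerate(scores) if j != k)
    return k, scores[k], scores[k] - runner_up


def latent_target(pssm: np.ndarray, peptide: str) -> Tuple[int, float]:
    """Noise-free (true core offset, target) for one peptide."""
    k, s = best_core(pssm, peptide)
    t = 1.0 / (1.0 + np.exp(-(s - SCORE_CENTER) / SCORE_SCALE))
    return k, float(t)


def generate_records(
    allele: SyntheticAllele,
    n_peptides: int,
    length_range: Tuple[int, int] = (9, 21),
    noise_sd: float = 0.05,
    seed: int = 0,
    base: float = DEFAULT_BASE,
    min_core_margin: float = 1.0,
) -> List[SyntheticRecord]:
    """Random uniform-residue peptides scored against the allele's motif.

    Peptides whose planted core is ambiguous — best offset beating the
    runner-up by less than ``min_core_margin`` score units — are resampled,
    so every record's true register is well defined (set 0 to disable).
    """
    lo, hi = length_range
    if lo < CORE_LENGTH:
        raise ValueError(f"minimum length must be >= {CORE_LENGTH}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for _ in range(n_peptides):
        while True:
            length = int(rng.integers(lo, hi + 1))
            peptide = "".join(rng.choice(aa, size=length))
            k, _, margin = _best_core_margin(allele.pssm, peptide)
            if margin >= min_core_margin:
                break
        _, t = latent_target(allele.pssm, peptide)
        if noise_sd > 0:
            t = float(np.clip(t + rng.normal(0.0, noise_sd), 0.0, 1.0))
        affinity = target_to_affinity(t, base)
        records.append(
            SyntheticRecord(
                peptide=peptide,
                allele=allele.name,
                affinity_nM=affinity,
                target=affinity_to_target(affinity, base),
                true_core_offset=k,
            )
        )
    return records


def generate_dataset(
    n_alleles: int,
    n_peptides: int,
    seed: int = 0,
    mutation_rate: float = 0.15,
    length_range: Tuple[int, int] = (9, 21),
    noise_sd: float = 0.05,
    base: float = DEFAULT_BASE,
) -> Tuple[List[SyntheticAllele], List[SyntheticRecord]]:
    """Alleles plus ``n_peptides`` records per allele, one call."""
    alleles = generate_alleles(n_alleles, seed=seed, mutation_rate=mutation_rate)
    records: List[SyntheticRecord] = []
    for i, al in enumerate(alleles):
        records.extend(
            generate_records(
                al, n_peptides, length_range=length_range, noise_sd=noise_sd,
                seed=seed * 100_003 + i + 1, base=base,
            )
        )
    return alleles, records


def allele_table(alleles: Sequence[SyntheticAllele]) -> Dict[str, Allele]:
    return {a.name: a.as_allele() for a in alleles}


def generate_ligand_fixture(
    allele: SyntheticAllele,
    protein_len: int = 120,
    n_proteins: int = 10,
    ligand_len_range: Tuple[int, int] = (12, 18),
    seed: int = 0,
) -> Tuple[Dict[str, str], List[LigandRecord]]:
    """Random source proteins, each with one high-scoring implanted ligand.

    The implanted window is built around a core sampled greedily from the
    allele's PSSM (per-position softmax, inverse-temperature 3) with
    random flanks, then written into the protein at a random position;
    that window is the annotated ligand.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins: Dict[str, str] = {}
    ligands: List[LigandRecord] = []
    for i in range(n_proteins):
        pid = f"PROT-{i:03d}"
        protein = list(rng.choice(aa, size=protein_len))
        llen = int(rng.integers(ligand_len_range[0], ligand_len_range[1] + 1))
        n_flank = int(rng.integers(0, llen - CORE_LENGTH + 1))
        core = []
        for pos in range(CORE_LENGTH):
            w = np.exp(3.0 * allele.pssm[pos])
            core.append(str(rng.choice(aa, p=w / w.sum())))
        ligand = (
            "".join(rng.choice(aa, size=n_flank))
            + "".join(core)
            + "".join(rng.choice(aa, size=llen - CORE_LENGTH - n_flank))
        )
        start = int(rng.integers(0, protein_len - llen + 1))
        protein[start : start + llen] = list(ligand)
        proteins[pid] = "".join(protein)
        ligands.append(LigandRecord(pid, ligand, allele.name))
    return proteins, ligands


# ---------------------------------------------------------------------------
# writing fixture files in the pipeline's own formats


def write_dataset(
    outdir,
    alleles: Sequence[SyntheticAllele],
    records: Sequence[BindingRecord],
    proteins: Dict[str, str] | None = None,
    ligands: Sequence[LigandRecord] | None = None,
) -> None:
    """Write binding.tsv, pseudo.txt and optional proteins.fasta/ligands.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "binding.tsv", "w") as fh:
        fh.write("peptide\tallele\taffinity_nM\n")
        for r in records:
            fh.write(f"{r.peptide}\t{r.allele}\t{r.affinity_nM:.4f}\n")
    with open(outdir / "pseudo.txt", "w") as fh:
        for a in alleles:
            fh.write(f"{a.name}\t{a.pseudo}\n")
    if proteins is not None:
        with open(outdir / "proteins.fasta", "w") as fh:
            for pid, seq in proteins.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    if ligands is not None:
        with open(outdir / "ligands.tsv", "w") as fh:
            fh.write("protein_id\tligand\tallele\n")
            for lig in ligands:
                fh.write(f"{lig.protein_id}\t{lig.ligand}\t{lig.allele}\n")
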
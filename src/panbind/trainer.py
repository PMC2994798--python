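"""Concurrent core alignment and network training.

Each training cycle visits every record once in random order.  For a
record, the 9-mer binding core is re-identified as the highest-scoring
offset under the *current* weights, and one online gradient step is then
taken on that offset's encoding.  The procedure thus estimates the
binding register and the network weights simultaneously.

The full model is an ensemble: for every cross-validation fold,
len(schemes) * n_seeds networks are trained on the remaining folds.

Candidate-offset encodings are static per (record, scheme), so they are
precomputed once and the cycle loop runs over a flat matrix.  The inner
loop is JIT-compiled with numba when available; a pure-numpy fallback
implements identical arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

from panbind.data_io import Allele, BindingRecord, CORE_LENGTH, DEFAULT_BASE
from panbind.encoding import (
    DEFAULT_FEATURES,
    EncodingScheme,
    FeatureConfig,
    SCHEMES,
    encode_all_offsets,
    input_length,
)
from panbind.neuralnet import (
    DEFAULT_N_HIDDEN,
    DEFAULT_WEIGHT_RANGE,
    Network,
    forward_batch,
    init_network,
    load_network,
    save_network,
)

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class TrainConfig:
    """All knobs of ensemble training, with the published defaults."""

    n_cycles: int = 500
    n_seeds: int = 10
    schemes: Tuple[str, ...] = ("sparse", "blosum")
    n_hidden: int = DEFAULT_N_HIDDEN
    n_folds: int = 5
    learning_rate: float = 0.1
    base: float = DEFAULT_BASE
    weight_range: float = DEFAULT_WEIGHT_RANGE
    master_seed: int = 1

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.schemes:
            raise ValueError("at least one encoding scheme is required")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")

    @property
    def networks_per_configuration(self) -> int:
        return len(self.schemes) * self.n_seeds

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schemes"] = list(d["schemes"])
        return d


def network_seed(master_seed: int, fold: int, scheme_index: int, k: int) -> int:
    """Deterministic per-network seed.

    seed = master*1000003 + fold*8191 + scheme_index*127 + k, mod 2^31.
    Distinct (fold, scheme, k) triples give distinct seeds for any
    realistic configuration size.
    """
    return (master_seed * 1_000_003 + fold * 8191 + scheme_index * 127 + k) % (2**31)


# ---------------------------------------------------------------------------
# inner training loop


def _train_loop_numpy(X, starts, targets, orders, w1, b1, w2, b2, lr):
    n = targets.shape[0]
    for c in range(orders.shape[0]):
        order = orders[c]
        for ii in range(n):
            r = order[ii]
            Xi = X[starts[r] : starts[r + 1]]
            H = 1.0 / (1.0 + np.exp(-(Xi @ w1 + b1)))
            O = 1.0 / (1.0 + np.exp(-(H @ w2 + b2)))
            k = int(np.argmax(O))
            o = O[k]
            h = H[k]
            do = (o - targets[r]) * o * (1.0 - o)
            dh = do * w2 * h * (1.0 - h)
            w1 -= lr * Xi[k][:, None] * dh
            b1 -= lr * dh
            w2 -= lr * do * h
            b2[0] -= lr * do
    return b2


if _HAVE_NUMBA:

    @njit(cache=True)
    def _train_loop_numba(X, starts, targets, orders, w1, b1, w2, b2, lr):  # pragma: no cover
        n = targets.shape[0]
        nh = w1.shape[1]
        d = w1.shape[0]
        dh = np.empty(nh)
        for c in range(orders.shape[0]):
            order = orders[c]
            for ii in range(n):
                r = order[ii]
                s = starts[r]
                e = starts[r + 1]
                Xi = X[s:e]
                H = np.dot(Xi, w1)
                m = e - s
                best = -1.0
                k = 0
                o = 0.0
                for j in range(m):
                    acc = b2[0]
                    for t in range(nh):
                        H[j, t] = 1.0 / (1.0 + np.exp(-(H[j, t] + b1[t])))
                        acc += H[j, t] * w2[t]
                    oj = 1.0 / (1.0 + np.exp(-acc))
                    if oj > best:
                        best = oj
                        k = j
                        o = oj
                do = (o - targets[r]) * o * (1.0 - o)
                xk = Xi[k]
                for t in range(nh):
                    h = H[k, t]
                    dh[t] = lr * do * w2[t] * h * (1.0 - h)
                    b1[t] -= dh[t]
                    w2[t] -= lr * do * h
                for i in range(d):  # row-major order for the w1 update
                    xi = xk[i]
                    for t in range(nh):
                        w1[i, t] -= dh[t] * xi
                b2[0] -= lr * do
        return b2


def _run_cycles(X, starts, targets, orders, net: Network, lr: float) -> None:
    """Dispatch the cycle loop to numba when available."""
    b2 = np.array([net.b2])
    loop = _train_loop_numba if _HAVE_NUMBA else _train_loop_numpy
    loop(X, starts, targets, orders, net.w1, net.b1, net.w2, b2, lr)
    net.b2 = float(b2[0])


# ---------------------------------------------------------------------------
# encoding cache


def _resolve_scheme(scheme) -> EncodingScheme:
    if isinstance(scheme, EncodingScheme):
        return scheme
    return SCHEMES[scheme]


def build_offset_cache(
    records: Sequence[BindingRecord],
    allele_table: Dict[str, Allele],
    scheme,
    features: FeatureConfig = DEFAULT_FEATURES,
):
    """Precompute candidate-core encodings for every record.

    Returns (X, starts, targets): X stacks the per-offset encodings of all
    records; record r owns rows starts[r]:starts[r+1].
    """
    scheme = _resolve_scheme(scheme)
    blocks = []
    starts = np.zeros(len(records) + 1, dtype=np.int64)
    targets = np.empty(len(records))
    for r, rec in enumerate(records):
        allele = allele_table.get(rec.allele)
        if allele is None:
            raise KeyError(f"allele {rec.allele} has no pseudo sequence")
        block = encode_all_offsets(rec.peptide, allele, scheme, features)
        blocks.append(block)
        starts[r + 1] = starts[r] + block.shape[0]
        targets[r] = rec.target
    X = np.ascontiguousarray(np.concatenate(blocks, axis=0))
    return X, starts, targets


# ---------------------------------------------------------------------------
# public training API


def find_best_core(net: Network, peptide: str, allele: Allele, scheme) -> Tuple[int, float]:
    """Highest-scoring 9-mer offset under the current weights.

    Evaluates all len(peptide) - 8 offsets; ties go to the smallest offset.
    """
    scheme = _resolve_scheme(scheme)
    X = encode_all_offsets(peptide, allele, scheme)
    scores = forward_batch(net, X)
    k = int(np.argmax(scores))
    return k, float(scores[k])


def train_one(
    records: Sequence[BindingRecord],
    allele_table: Dict[str, Allele],
    scheme,
    seed: int,
    cfg: TrainConfig,
    features: FeatureConfig = DEFAULT_FEATURES,
) -> Network:
    """Train one network with the concurrent core/weight procedure.

    Deterministic given (record order, seed, cfg): the seed drives both
    weight initialization and the per-cycle shuffles.  n_cycles == 0
    returns the freshly initialized network.
    """
    if not records:
        raise ValueError("no training records")
    scheme = _resolve_scheme(scheme)
    X, starts, targets = build_offset_cache(records, allele_table, scheme, features)
    rng = np.random.default_rng(seed)
    net = init_network(
        X.shape[1],
        n_hidden=cfg.n_hidden,
        seed=seed,
        weight_range=cfg.weight_range,
        scheme=scheme.kind,
        rng=rng,
    )
    if cfg.n_cycles > 0:
        orders = np.stack(
            [rng.permutation(len(records)) for _ in range(cfg.n_cycles)]
        ).astype(np.int64)
        _run_cycles(X, starts, targets, orders, net, cfg.learning_rate)
    return net


def mse_at_assigned_cores(
    net: Network,
    records: Sequence[BindingRecord],
    allele_table: Dict[str, Allele],
    scheme,
) -> float:
    """Mean squared error at each record's current best core."""
    scheme = _resolve_scheme(scheme)
    X, starts, targets = build_offset_cache(records, allele_table, scheme)
    preds = forward_batch(net, X)
    best = np.array(
        [preds[starts[r] : starts[r + 1]].max() for r in range(len(records))]
    )
    return float(np.mean((best - targets) ** 2))


# ---------------------------------------------------------------------------
# data partitioning for cross-validation


def _shared_kmer_clusters(peptides: Sequence[str], motif_len: int) -> List[List[str]]:
    """Single-linkage clusters of peptides sharing any identical k-mer."""
    parent = list(range(len(peptides)))

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = root(i), root(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    kmer_owner: Dict[str, int] = {}
    for i, pep in enumerate(peptides):
        for p in range(len(pep) - motif_len + 1):
            kmer = pep[p : p + motif_len]
            j = kmer_owner.setdefault(kmer, i)
            if j != i:
                union(i, j)
    clusters: Dict[int, List[str]] = {}
    for i, pep in enumerate(peptides):
        clusters.setdefault(root(i), []).append(pep)
    return [clusters[k] for k in sorted(clusters)]


def partition_data(
    records: Sequence[BindingRecord],
    n_folds: int,
    motif_len: int = CORE_LENGTH,
    seed: int = 0,
) -> np.ndarray:
    """Assign a fold label to every record, minimizing fold overlap.

    Peptides sharing any identical ``motif_len``-mer are single-linkage
    clustered and a cluster never straddles folds.  Clusters are placed in
    descending size (records) onto the currently smallest fold; the seed
    shuffles the order among equal-sized clusters.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    peptides = sorted({rec.peptide for rec in records})
    clusters = _shared_kmer_clusters(peptides, motif_len)
    if n_folds > len(clusters):
        raise ValueError(
            f"cannot make {n_folds} folds from {len(clusters)} sequence clusters"
        )
    weight: Dict[str, int] = {}
    for rec in records:
        weight[rec.peptide] = weight.get(rec.peptide, 0) + 1

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    sizes = np.array([sum(weight[p] for p in clusters[i]) for i in order])
    ranked = order[np.argsort(-sizes, kind="stable")]

    fold_of_peptide: Dict[str, int] = {}
    fold_load = np.zeros(n_folds, dtype=np.int64)
    for ci in ranked:
        f = int(np.argmin(fold_load))
        for pep in clusters[ci]:
            fold_of_peptide[pep] = f
        fold_load[f] += sum(weight[p] for p in clusters[ci])
    return np.array([fold_of_peptide[rec.peptide] for rec in records], dtype=np.int64)


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class Ensemble:
    """A bag of trained networks predicted over jointly.

    ``fold`` is the held-out fold this ensemble predicts (None for pooled
    or leave-one-out ensembles).
    """

    networks: List[Network]
    config: TrainConfig
    allele_table: Dict[str, Allele]
    fold: int | None = None

    @classmethod
    def pooled(cls, ensembles: Sequence["Ensemble"]) -> "Ensemble":
        """Merge per-fold ensembles into one released predictor."""
        nets = [n for e in ensembles for n in e.networks]
        return cls(nets, ensembles[0].config, ensembles[0].allele_table, fold=None)


def train_networks(
    records: Sequence[BindingRecord],
    allele_table: Dict[str, Allele],
    cfg: TrainConfig,
    fold: int = 0,
) -> List[Network]:
    """Train len(schemes) * n_seeds networks on one training set."""
    nets = []
    for si, scheme in enumerate(cfg.schemes):
        for k in range(cfg.n_seeds):
            seed = network_seed(cfg.master_seed, fold, si, k)
            nets.append(train_one(records, allele_table, scheme, seed, cfg))
    return nets


@dataclass
class TrainResult:
    """Per-fold ensembles plus the concatenated cross-validated predictions."""

    ensembles: List[Ensemble]
    fold_labels: np.ndarray
    cv_predictions: list  # PredictionResult per record, aligned with input order

    def pooled_ensemble(self) -> Ensemble:
        return Ensemble.pooled(self.ensembles)


def train_ensemble(
    records: Sequence[BindingRecord],
    allele_table: Dict[str, Allele],
    cfg: TrainConfig,
) -> TrainResult:
    """Full cross-validated training.

    For each fold, trains an ensemble on the union of the other folds and
    predicts the held-out fold; every record receives exactly one
    cross-validated prediction.
    """
    from panbind.predictor import predict

    records = list(records)
    fold_labels = partition_data(records, cfg.n_folds, seed=cfg.master_seed)
    ensembles: List[Ensemble] = []
    cv_predictions = [None] * len(records)
    for f in range(cfg.n_folds):
        train_recs = [r for r, lab in zip(records, fold_labels) if lab != f]
        nets = train_networks(train_recs, allele_table, cfg, fold=f)
        ens = Ensemble(nets, cfg, allele_table, fold=f)
        ensembles.append(ens)
        for i, (rec, lab) in enumerate(zip(records, fold_labels)):
            if lab == f:
                cv_predictions[i] = predict(ens, rec.peptide, rec.allele)
        logger.info("fold %d: trained %d networks on %d records", f, len(nets), len(train_recs))
    return TrainResult(ensembles, fold_labels, cv_predictions)


# ---------------------------------------------------------------------------
# model persistence


def save_model(dirpath, result: TrainResult) -> None:
    """Write all networks, the config, and the fold assignment to a directory."""
    dirpath = Path(dirpath)
    (dirpath / "networks").mkdir(parents=True, exist_ok=True)
    cfg = result.ensembles[0].config
    (dirpath / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    (dirpath / "folds.json").write_text(json.dumps(result.fold_labels.tolist()))
    for ens in result.ensembles:
        fold = ens.fold if ens.fold is not None else 0
        for j, net in enumerate(ens.networks):
            save_network(net, dirpath / "networks" / f"net_f{fold}_{j:03d}.json")


def load_model(dirpath, allele_table: Dict[str, Allele]) -> Ensemble:
    """Load a saved model directory as one pooled ensemble."""
    dirpath = Path(dirpath)
    cfg = TrainConfig.from_yaml(dirpath / "config.yaml")
    paths = sorted((dirpath / "networks").glob("net_*.json"))
    if not paths:
        raise FileNotFoundError(f"{dirpath}: no serialized networks found")
    nets = [load_network(p) for p in paths]
    return Ensemble(nets, cfg, allele_table, fold=None)
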
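from dataclasses import replace

import numpy as np
import pytest

from panbind import synthetic
from panbind.data_io import Allele, BindingRecord, affinity_to_target
from panbind.encoding import SCHEMES, encode_example
from panbind.neuralnet import forward, init_network
from panbind.trainer import (
    TrainConfig,
    _train_loop_numpy,
    build_offset_cache,
    find_best_core,
    mse_at_assigned_cores,
    network_seed,
    partition_data,
    train_ensemble,
    train_networks,
    train_one,
)


def _rec(peptide, allele="A1", affinity=50.0):
    return BindingRecord(peptide, allele, affinity, affinity_to_target(affinity))


class TestTrainConfig:
    def test_defaults_match_published_ensemble(self):
        cfg = TrainConfig()
        assert cfg.n_cycles == 500
        assert cfg.n_hidden == 40
        assert cfg.n_folds == 5
        assert cfg.networks_per_configuration == 20

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(n_folds=1)
        with pytest.raises(ValueError):
            TrainConfig(schemes=())
        with pytest.raises(ValueError):
            TrainConfig(schemes=("sparse", "bogus"))

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = TrainConfig(n_cycles=7, schemes=("blosum",))
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert TrainConfig.from_yaml(path) == cfg

    def test_network_seeds_distinct(self):
        seeds = {
            network_seed(1, f, s, k)
            for f in range(5)
            for s in range(2)
            for k in range(10)
        }
        assert len(seeds) == 100


class TestFindBestCore:
    def test_nine_mer_offset_zero(self, drb_alleles):
        net = init_network(646, 4, seed=0)
        off, _ = find_best_core(net, "PKYVKQNTL", drb_alleles["DRB1*0101"], "sparse")
        assert off == 0

    def test_matches_exhaustive_scan(self, drb_alleles):
        # independent oracle: loop offsets, encode, forward, take argmax
        net = init_network(646, 8, seed=3, weight_range=0.5)
        allele = drb_alleles["DRB1*0101"]
        pep = "PKYVKQNTLKLATRS"  # 15-mer -> 7 candidates
        scheme = SCHEMES["sparse"]
        oracle = [
            forward(net, encode_example(pep, k, allele, scheme)) for k in range(7)
        ]
        assert len(oracle) == len(pep) - 8
        off, score = find_best_core(net, pep, allele, scheme)
        assert off == int(np.argmax(oracle))
        assert score == pytest.approx(max(oracle), abs=1e-12)

    def test_too_short_rejected(self, drb_alleles):
        net = init_network(646, 4, seed=0)
        with pytest.raises(ValueError):
            find_best_core(net, "PKYVKQNT", drb_alleles["DRB1*0101"], "sparse")


class TestTrainOne:
    def test_deterministic(self, tiny_data, tiny_cfg):
        _, records, table = tiny_data
        a = train_one(records[:40], table, "sparse", 11, tiny_cfg)
        b = train_one(records[:40], table, "sparse", 11, tiny_cfg)
        assert np.array_equal(a.w1, b.w1)
        assert np.array_equal(a.b1, b.b1)
        assert np.array_equal(a.w2, b.w2)
        assert a.b2 == b.b2

    def test_zero_cycles_returns_initialized_network(self, tiny_data, tiny_cfg):
        _, records, table = tiny_data
        cfg = replace(tiny_cfg, n_cycles=0)
        net = train_one(records[:10], table, "sparse", 13, cfg)
        ref = init_network(646, cfg.n_hidden, seed=13, weight_range=cfg.weight_range)
        assert np.array_equal(net.w1, ref.w1)
        assert net.b2 == ref.b2

    def test_missing_allele_rejected(self, tiny_data, tiny_cfg):
        _, records, table = tiny_data
        bad = dict(table)
        del bad[records[0].allele]
        with pytest.raises(KeyError):
            train_one(records[:10], bad, "sparse", 1, tiny_cfg)

    def test_single_allele_motif_learned(self):
        # planted-motif toy set: training-set PCC must exceed 0.8
        from panbind.metrics import pcc

        alleles = synthetic.generate_alleles(1, seed=5)
        records = synthetic.generate_records(alleles[0], 300, noise_sd=0.05, seed=5)
        table = synthetic.allele_table(alleles)
        cfg = TrainConfig(n_cycles=60, n_seeds=1, schemes=("sparse",))
        net = train_one(records, table, "sparse", 21, cfg)
        scores = [
            find_best_core(net, r.peptide, table[r.allele], "sparse")[1]
            for r in records
        ]
        assert pcc(scores, [r.target for r in records]) > 0.8

    def test_training_loss_mostly_nonincreasing(self):
        # loss at assigned cores, sampled along one trajectory via the
        # shared-prefix determinism of the cycle shuffles
        alleles = synthetic.generate_alleles(1, seed=5)
        records = synthetic.generate_records(alleles[0], 150, noise_sd=0.05, seed=6)
        table = synthetic.allele_table(alleles)
        losses = []
        for n_cycles in (0, 25, 50, 75, 100):
            cfg = TrainConfig(n_cycles=n_cycles, n_seeds=1, schemes=("sparse",))
            net = train_one(records, table, "sparse", 3, cfg)
            losses.append(mse_at_assigned_cores(net, records, table, "sparse"))
        drops = sum(b <= a for a, b in zip(losses, losses[1:]))
        assert drops >= 3, losses


class TestLoopEquivalence:
    def test_numba_and_numpy_paths_agree(self, tiny_data):
        numba = pytest.importorskip("numba")
        from panbind.trainer import _train_loop_numba

        _, records, table = tiny_data
        X, starts, targets = build_offset_cache(records[:30], table, "sparse")
        rng = np.random.default_rng(0)
        orders = np.stack([rng.permutation(30) for _ in range(5)]).astype(np.int64)

        def run(loop):
            r = np.random.default_rng(42)
            w1 = r.normal(size=(X.shape[1], 6))
            b1 = r.normal(size=6)
            w2 = r.normal(size=6)
            b2 = np.array([0.1])
            loop(X, starts, targets, orders, w1, b1, w2, b2, 0.05)
            return w1, b1, w2, b2

        res_np = run(_train_loop_numpy)
        res_nb = run(_train_loop_numba)
        for a, b in zip(res_np, res_nb):
            assert a == pytest.approx(b, rel=1e-10, abs=1e-12)


class TestPartitionData:
    def test_shared_nine_mer_same_fold(self):
        shared = "PKYVKQNTL"
        records = [_rec(shared + "AAA"), _rec("CDE" + shared)]
        # pad with unrelated peptides so 2 folds are constructible
        rng = np.random.default_rng(1)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            records.append(_rec("".join(rng.choice(aa, size=13))))
        labels = partition_data(records, 2, seed=0)
        assert labels[0] == labels[1]

    def test_unique_peptides_balanced(self):
        rng = np.random.default_rng(2)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        records = [_rec("".join(rng.choice(aa, size=12))) for _ in range(23)]
        labels = partition_data(records, 5, seed=1)
        counts = np.bincount(labels, minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_matches_connected_components_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peptides = ["".join(rng.choice(aa, size=rng.integers(9, 16))) for _ in range(40)]
        # force some shared 9-mers
        for i in range(0, 30, 3):
            peptides.append(peptides[i][:9] + "".join(rng.choice(aa, size=4)))
        records = [_rec(p) for p in peptides]
        labels = partition_data(records, 3, seed=4)
        # oracle: pairwise shared-9-mer graph, connected components
        g = nx.Graph()
        g.add_nodes_from(set(peptides))
        uniq = sorted(set(peptides))
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                kmers_a = {a[j : j + 9] for j in range(len(a) - 8)}
                if any(b[j : j + 9] in kmers_a for j in range(len(b) - 8)):
                    g.add_edge(a, b)
        label_of = {r.peptide: l for r, l in zip(records, labels)}
        for comp in nx.connected_components(g):
            assert len({label_of[p] for p in comp}) == 1

    def test_more_folds_than_clusters_rejected(self):
        records = [_rec("PKYVKQNTLAAA"), _rec("PKYVKQNTLCCC")]
        with pytest.raises(ValueError):
            partition_data(records, 2)

    def test_deterministic_given_seed(self, tiny_data):
        _, records, _ = tiny_data
        a = partition_data(records, 3, seed=9)
        b = partition_data(records, 3, seed=9)
        assert np.array_equal(a, b)


class TestTrainEnsemble:
    def test_counts_and_partition(self, tiny_data):
        _, records, table = tiny_data
        cfg = TrainConfig(
            n_cycles=2, n_seeds=2, schemes=("sparse", "blosum"), n_folds=3, master_seed=5
        )
        result = train_ensemble(records, table, cfg)
        assert len(result.ensembles) == 3
        for ens in result.ensembles:
            assert len(ens.networks) == cfg.networks_per_configuration == 4
        # every record predicted exactly once, by its own fold's ensemble
        assert all(p is not None for p in result.cv_predictions)
        assert len(result.cv_predictions) == len(records)
        for rec, pred in zip(records, result.cv_predictions):
            assert pred.peptide == rec.peptide
            assert pred.allele == rec.allele

    def test_smoke_learns_something(self, tiny_data):
        from panbind.metrics import pcc

        _, records, table = tiny_data
        cfg = TrainConfig(n_cycles=30, n_seeds=1, schemes=("sparse",), n_folds=3, master_seed=5)
        result = train_ensemble(records, table, cfg)
        scores = [p.score for p in result.cv_predictions]
        assert pcc(scores, [r.target for r in records]) > 0.0

    def test_train_networks_one_per_scheme_seed(self, tiny_data):
        _, records, table = tiny_data
        cfg = TrainConfig(n_cycles=1, n_seeds=3, schemes=("sparse", "blosum"))
        nets = train_networks(records[:20], table, cfg)
        assert len(nets) == 6
        assert sorted({n.scheme for n in nets}) == ["blosum", "sparse"]
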
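import numpy as np
import pytest

from panbind import synthetic
from panbind.data_io import Allele
from panbind.trainer import TrainConfig


@pytest.fixture
def drb_alleles():
    """Two hand-written alleles with 21-mer pseudo sequences."""
    return {
        "DRB1*0101": Allele("DRB1*0101", "FLEFFIAQGALANIAVDKANV"),
        "DRB1*0301": Allele("DRB1*0301", "FLDYFHHQGALANIAVDKANV"),
    }


@pytest.fixture(scope="session")
def tiny_data():
    """3 synthetic alleles x 60 peptides; enough signal to learn from."""
    alleles, records = synthetic.generate_dataset(3, 60, seed=7, noise_sd=0.05)
    return alleles, records, synthetic.allele_table(alleles)


@pytest.fixture(scope="session")
def tiny_cfg():
    return TrainConfig(
        n_cycles=15, n_seeds=1, schemes=("sparse",), n_folds=3, master_seed=7
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_data, tiny_cfg):
    """A small 2-network ensemble trained on the tiny dataset."""
    from panbind.trainer import Ensemble, train_networks
    from dataclasses import replace

    alleles, records, table = tiny_data
    cfg = replace(tiny_cfg, n_seeds=2)
    nets = train_networks(records, table, cfg)
    return Ensemble(nets, cfg, table)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
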
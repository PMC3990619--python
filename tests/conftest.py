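import numpy as np
import pytest

import barcodekit as bk
from barcodekit.simulate import draw_root_sequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140417)


@pytest.fixture(scope="session")
def clean_dataset():
    """Small gap-clean dataset: 12 species, one deep split, QC failures."""
    cfg = bk.SimConfig(
        n_species=12,
        seed=5,
        n_deep_split=1,
        qc_short_frac=0.03,
        qc_ambig_frac=0.02,
        qc_pseudo_frac=0.02,
        planted_indels=(bk.PlantedIndel(37, 1, "insertion", 2),),
    )
    return cfg, bk.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def stop_free_seq():
    """Deterministic 648-bp stop-free coding sequence."""
    return draw_root_sequence(0.37, 216, np.random.default_rng(99))


def make_matrix(ids, dense):
    """DistanceMatrix from a dense array with NaN marking undefined."""
    d = np.asarray(dense, dtype=float)
    defined = ~np.isnan(d)
    return bk.DistanceMatrix(
        ids=list(ids), d=d, defined=defined, overlap=np.full(d.shape, 648, dtype=np.int64)
    )
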
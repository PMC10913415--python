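import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from loyscan.io import CellMetadata, CountBundle, GeneAnnotation
from loyscan.simulate import SimParams, simulate_dataset


def make_bundle(genes, cells, layers):
    """Build a CountBundle from dense nested lists, one per layer."""
    return CountBundle(
        genes=np.array(genes, dtype=object),
        cells=np.array(cells, dtype=object),
        layers={k: sp.csr_matrix(np.array(v)) for k, v in layers.items()},
    )


def make_annotation(rows):
    """rows: (id, chromosome, is_msy, is_par, is_mito)."""
    return GeneAnnotation(
        pd.DataFrame(
            [(r[0], r[0], r[1], r[2], r[3], r[4]) for r in rows],
            columns=["id", "symbol", "chromosome", "is_msy", "is_par", "is_mito"],
        )
    )


def make_metadata(rows):
    """rows: (barcode, sample_id, sex, cluster)."""
    return CellMetadata(
        pd.DataFrame(rows, columns=["barcode", "sample_id", "sex", "cluster"])
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter cohort shared across tests (seed 11)."""
    params = SimParams(seed=11)
    return simulate_dataset(params), params


@pytest.fixture(scope="session")
def ambient_sim():
    """A noisy public-style cohort with female MSY background (seed 7)."""
    params = SimParams(
        n_samples_male=10,
        n_samples_female=10,
        cells_per_sample=800,
        ambient_msy_rate=0.3,
        seed=7,
    )
    return simulate_dataset(params), params


@pytest.fixture
def tiny_msy_bundle():
    """3 genes (1 MSY, 1 PAR, 1 autosomal) x 4 cells with known counts."""
    bundle = make_bundle(
        genes=["RPS4Y1", "CD99", "ACTB"],
        cells=["c1", "c2", "c3", "c4"],
        layers={
            "spliced": [[1, 0, 0, 2], [10, 10, 10, 10], [5, 5, 5, 5]],
            "unspliced": [[0, 0, 1, 0], [0, 0, 0, 0], [1, 1, 1, 1]],
        },
    )
    ann = make_annotation(
        [
            ("RPS4Y1", "chrY", 1, 0, 0),
            ("CD99", "chrX;chrY", 0, 1, 0),
            ("ACTB", "chr7", 0, 0, 0),
        ]
    )
    meta = make_metadata(
        [
            ("c1", "s1", "male", "C0"),
            ("c2", "s1", "male", "C0"),
            ("c3", "s1", "male", "C0"),
            ("c4", "s2", "female", "C0"),
        ]
    )
    return bundle, ann, meta
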
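import numpy as np
import pytest


@pytest.fixture
def separable_clusters():
    """Two tight, far-apart clusters: any sensible classifier gets them right.

    Cluster scale 0.1, separation 10 — three orders of magnitude of margin.
    """
    rng = np.random.default_rng(42)
    n_per = 10
    X0 = rng.normal(0.0, 0.1, size=(n_per, 2))
    X1 = rng.normal(0.0, 0.1, size=(n_per, 2)) + np.array([10.0, 10.0])
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n_per)
    return X, y


@pytest.fixture
def spherical_data():
    """Class-conditional radial structure with equal means: no linear signal.

    Poor class (1) concentrated near the origin (sd 0.25), good class (0)
    spread N(0, 1) around it in 3 dimensions.
    """

    def make(n_good=100, n_poor=50, p=3, seed=0, spread=0.25):
        rng = np.random.default_rng(seed)
        Xg = rng.normal(0.0, 1.0, size=(n_good, p))
        Xp = rng.normal(0.0, spread, size=(n_poor, p))
        X = np.vstack([Xg, Xp])
        y = np.repeat([0, 1], [n_good, n_poor])
        perm = rng.permutation(len(y))
        return X[perm], y[perm]

    return make


@pytest.fixture
def expression_tsv(tmp_path):
    """3-gene x 4-sample expression TSV on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tS1\tS2\tS3\tS4\n"
        "G1\t0.0\t1.0\t3.0\t7.0\n"
        "G2\t1.5\t2.5\t0.5\t3.5\n"
        "G3\t2.0\t2.0\t1.0\t4.0\n"
    )
    return path


@pytest.fixture
def phenotype_csv(tmp_path):
    path = tmp_path / "pheno.csv"
    path.write_text(
        "sample_id,outcome,time,event\n"
        "S1,good,5.0,0\n"
        "S2,poor,1.2,1\n"
        "S3,good,4.1,1\n"
        "S4,good,6.0,0\n"
        "S5,poor,0.8,1\n"
    )
    return path
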
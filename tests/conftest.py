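import numpy as np
import pytest

from drugmtl import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """Fully observed low-rank cohort at unit-test scale."""
    spec = SyntheticSpec(
        n_cells=60, n_features=25, n_tasks=6, rank=2, noise_sd=0.5, seed=7
    )
    return generate(spec)


@pytest.fixture
def tiny_tables(tmp_path):
    """3x2 feature and response TSVs on disk."""
    fpath = tmp_path / "X.tsv"
    fpath.write_text("\tg1\tg2\na\t1.0\t0.5\nb\t2.0\t0.0\nc\t-1.0\t1.5\n")
    rpath = tmp_path / "Y.tsv"
    rpath.write_text("\td1\td2\na\t0.1\tNA\nb\t0.2\t1.0\nc\t0.3\t2.0\n")
    return fpath, rpath
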
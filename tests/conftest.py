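import numpy as np
import pandas as pd
import pytest

from chemoclock.chem import load_config
from chemoclock.features import ChromatographicRun


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_run(sample_id, role, strain, replicate, rows):
    """rows: iterable of (mz, rt_min, area)."""
    return ChromatographicRun(
        sample_id=sample_id,
        role=role,
        strain=strain,
        replicate=replicate,
        features=pd.DataFrame(rows, columns=["mz", "rt_min", "area"]),
    )


@pytest.fixture
def toy_runs():
    """Two strains x two replicates plus one blank; known grouping truth.

    Features A (500.0, 5.0) and B (600.0, 8.0) occur in both strains,
    C (700.0, 10.0) only in strain s2, D (550.0, 6.0) is medium background
    present in the blank at a comparable level.
    """
    a, b, c, d = (500.0, 5.0), (600.0, 8.0), (700.0, 10.0), (550.0, 6.0)
    runs = []
    for strain, feats in (
        ("s1", [a, b, d]),
        ("s2", [a, b, c, d]),
    ):
        for rep in (1, 2):
            rows = [
                (mz * (1 + 1e-6), rt + 0.02, 5e7 + 1e6 * rep) for mz, rt in feats
            ]
            runs.append(make_run(f"{strain}_r{rep}", "algal", strain, rep, rows))
    runs.append(make_run("blank_r1", "blank", None, 1, [(d[0], d[1], 4e7)]))
    return runs
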
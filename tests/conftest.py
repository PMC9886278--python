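import numpy as np
import pytest

import sarcopaint as sp
from sarcopaint.pipeline import analyze_myofibril


@pytest.fixture(scope="session")
def small_sim():
    """A 12-sarcomere two-epitope myofibril shared across tests."""
    cfg = sp.SimConfig(n_sarcomeres=12, seed=7)
    table, pick, truth = sp.simulate_myofibril(cfg)
    return cfg, table, pick, truth


@pytest.fixture(scope="session")
def analyzed(small_sim):
    cfg, table, pick, truth = small_sim
    res = analyze_myofibril(
        [table], pick, {"ch0": ["sls_nterm", "sls_cterm"]})
    return res, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_table(x, y, sx=None, sy=None, pixel_size_nm=130.0, channel_label=""):
    """Minimal localization table with defaulted bookkeeping columns."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    return sp.LocalizationTable(
        frame=np.zeros(n, dtype=int),
        x=x,
        y=np.asarray(y, dtype=float),
        photons=np.full(n, 1000.0),
        sx=np.ones(n) if sx is None else np.asarray(sx, dtype=float),
        sy=np.ones(n) if sy is None else np.asarray(sy, dtype=float),
        pixel_size_nm=pixel_size_nm,
        channel_label=channel_label,
    )
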
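import numpy as np
import pandas as pd
import pytest

from mrpipe.harmonize import HarmonizedSet


@pytest.fixture
def make_set():
    """Factory for HarmonizedSet objects from plain arrays."""

    def _make(bx, by, sx=None, sy=None, ids=None, eaf=None):
        bx = np.asarray(bx, dtype=float)
        by = np.asarray(by, dtype=float)
        k = len(bx)
        sx = np.full(k, 0.01) if sx is None else np.asarray(sx, dtype=float)
        sy = np.full(k, 0.01) if sy is None else np.asarray(sy, dtype=float)
        ids = ids or [f"rs{i}" for i in range(k)]
        eaf = np.full(k, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
        return HarmonizedSet(list(ids), bx, sx, by, sy, eaf)

    return _make


@pytest.fixture
def stats_table():
    """Factory for canonical summary-stat DataFrames."""

    def _make(n=5, seed=0, **overrides):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": ["1"] * n,
            "pos": np.arange(1, n + 1) * 100_000,
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "eaf": rng.uniform(0.1, 0.4, n),
            "beta": rng.normal(0.1, 0.02, n),
            "se": rng.uniform(0.01, 0.03, n),
            "pvalue": rng.uniform(1e-12, 1e-9, n),
            "n": [10_000] * n,
        })
        for k, v in overrides.items():
            df[k] = v
        return df

    return _make
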
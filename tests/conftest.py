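import numpy as np
import pytest

from sepscreen import MethylationMatrix, SampleSheet


@pytest.fixture
def small_matrix():
    """8 + 8 samples, 6 probes: nulls, one clear F>M probe, one with too few
    non-missing values in group M, and a duplicated null probe pair."""
    rng = np.random.default_rng(42)
    n_m = n_f = 8
    null_row = rng.uniform(0.2, 0.8, size=n_m + n_f)
    rows = {
        "cg_null_a": null_row,
        "cg_null_dup": null_row.copy(),
        "cg_null_b": rng.uniform(0.2, 0.8, size=n_m + n_f),
        "cg_f_high": np.concatenate([rng.uniform(0.05, 0.25, n_m), rng.uniform(0.6, 0.9, n_f)]),
        "cg_m_high": np.concatenate([rng.uniform(0.6, 0.9, n_m), rng.uniform(0.05, 0.25, n_f)]),
        "cg_sparse": np.concatenate([[0.5], [np.nan] * (n_m - 1), rng.uniform(0.2, 0.8, n_f)]),
    }
    probe_ids = list(rows)
    values = np.vstack(list(rows.values()))
    sample_ids = [f"M{i}" for i in range(n_m)] + [f"F{i}" for i in range(n_f)]
    matrix = MethylationMatrix(probe_ids, sample_ids, values)
    sheet = SampleSheet(sample_ids, ["M"] * n_m + ["F"] * n_f)
    return matrix, sheet
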
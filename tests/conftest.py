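import warnings

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    SimulationParams,
    build_block_dataset,
    normalize,
    run_sample_qc,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, QC'd and normalized, with ground truth."""
    params = SimulationParams(seed=11)
    ct, clinical, truth = simulate_cohort(params)
    clean, report = run_sample_qc(ct)
    expr = normalize(clean)
    return {
        "params": params, "ct": ct, "clinical": clinical, "truth": truth,
        "clean": clean, "report": report, "expr": expr,
    }


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return build_block_dataset(default_cohort["expr"], default_cohort["clinical"])


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down cohort for fast unit tests."""
    return SimulationParams(n_per_group=8, n_assays=60, n_signature=6, seed=5)


def make_ct(values: np.ndarray, assays=None, controls=None, doses=None):
    """Tiny CtMatrix factory for hand-built examples."""
    from mirsig.datatypes import CtMatrix, SampleMeta, meta_frame

    n, p = values.shape
    assays = assays or [f"assay{j}" for j in range(p)]
    ids = [f"s{i}" for i in range(n)]
    doses = doses if doses is not None else [0.0] * n
    meta = meta_frame([SampleMeta(i, "targeted", "D1", d) for i, d in zip(ids, doses)])
    vals = pd.DataFrame(values, index=ids, columns=assays)
    return CtMatrix(vals, meta, controls or {})


@pytest.fixture
def ct_factory():
    return make_ct
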
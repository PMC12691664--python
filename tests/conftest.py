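import numpy as np
import pandas as pd
import pytest

from dielomics import ExpressionMatrix, DEFAULT_PHASES, DEFAULT_TIMEPOINTS


def make_matrix(values, timepoints, replicates=None, phases=None, genes=None):
    """Build an ExpressionMatrix from a plain array and per-sample timepoints."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    assert len(timepoints) == n_samples
    if replicates is None:
        seen = {}
        replicates = []
        for tp in timepoints:
            seen[tp] = seen.get(tp, 0) + 1
            replicates.append(seen[tp])
    if phases is None:
        phases = [DEFAULT_PHASES.get(tp, "light") for tp in timepoints]
    samples = [f"{tp}_r{r}" for tp, r in zip(timepoints, replicates)]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {"timepoint": timepoints, "replicate": replicates, "phase": phases},
        index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture
def core_design_matrix():
    """12 samples over the 8 core time points is too thin; use 8 tps x 3 reps."""
    rng = np.random.default_rng(42)
    tps = [tp for tp in DEFAULT_TIMEPOINTS[:8] for _ in range(3)]
    vals = rng.lognormal(4, 1, size=(30, len(tps)))
    return make_matrix(vals, tps)
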
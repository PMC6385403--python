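import numpy as np
import pandas as pd
import pytest

from regencomp import SimulationConfig, ProgramSpec, run_comparison_pipeline
from regencomp.expr import CountMatrix, FRAGMENTS, TIMEPOINTS


def design_meta(reps=(1, 2)) -> pd.DataFrame:
    """Sample sheet for the full fragment x timepoint design."""
    rows, samples = [], []
    for frag in FRAGMENTS:
        for tp in TIMEPOINTS:
            for rep in reps:
                samples.append(f"{frag}_{tp}_r{rep}")
                rows.append((frag, tp, rep, f"b{rep}"))
    return pd.DataFrame(
        rows, index=pd.Index(samples, name="sample"),
        columns=["fragment", "timepoint", "replicate", "batch"],
    )


def make_count_matrix(values, genes=None, reps=(1,)) -> CountMatrix:
    """CountMatrix whose every sample column equals ``values``."""
    values = np.asarray(values)
    meta = design_meta(reps)
    if genes is None:
        genes = [f"g{i}" for i in range(len(values))]
    counts = pd.DataFrame(
        np.tile(values[:, None], (1, len(meta))), index=genes, columns=meta.index
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=9,
        n_genes_per_species=300,
        programs=(
            ProgramSpec("up_early", 30, 2.0, shared_across_species=True),
            ProgramSpec("down_early", 30, 2.0),
        ),
    )


@pytest.fixture(scope="session")
def default_report():
    """One full default-configuration pipeline run, shared across tests."""
    return run_comparison_pipeline(SimulationConfig(seed=7))
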
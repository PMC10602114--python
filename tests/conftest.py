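import numpy as np
import pandas as pd
import pytest

from togcn import ExpressionMatrix, SampleTable
from togcn.synthetic import SimConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_samples() -> SampleTable:
    rows = []
    for cond in ("embryonic", "juvenile"):
        for j, tp in enumerate(["T1", "T2", "T3", "T4", "T5"], start=1):
            for rep in (1, 2):
                rows.append(
                    {"sample_id": f"{cond}_{tp}_r{rep}", "condition": cond,
                     "timepoint": tp, "order": j, "replicate": rep}
                )
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def random_expression(rng) -> ExpressionMatrix:
    genes = [f"g{i:03d}" for i in range(30)]
    samples = [f"s{i}" for i in range(8)]
    vals = rng.gamma(2.0, 50.0, size=(30, 8))
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "TPM")


def small_sim_config(**overrides) -> SimConfig:
    """A down-scaled simulation for fast unit tests."""
    base = dict(
        n_levels=5,
        tfs_per_level=3,
        n_coexpressed_per_level=5,
        n_background_genes=200,
        n_shifted_tfs=2,
        shift_levels=3,
        noise_sd=0.0,
        # small gene universes estimate the upper quartile too coarsely to
        # undo planted library-size factors cleanly; unit tests isolate the
        # chain-recovery logic and leave the UQ correction to its own tests
        library_size_sd=0.0,
        planted_terms=[("term_mid", 3, 8)],
        n_null_terms=2,
        null_term_size=20,
        rng_seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def small_sim():
    return generate(small_sim_config())
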
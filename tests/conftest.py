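import numpy as np
import pandas as pd
import pytest

from fhsig import synthetic, workflow
from fhsig.config import SimulationConfig


@pytest.fixture(scope="session")
def default_bulk_run():
    """Full-default bulk simulation plus derived signatures (shared: expensive)."""
    cfg = SimulationConfig(seed=1)
    counts, meta, truth = synthetic.generate_bulk_experiment(cfg)
    sigs, outputs = workflow.derive_from_counts(counts, meta)
    return {
        "config": cfg,
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "signatures": sigs,
        "outputs": outputs,
    }


@pytest.fixture(scope="session")
def small_sc_config():
    """Desk-scale single-cell design: 3 planted clusters, 3 donors."""
    return SimulationConfig(
        seed=2,
        n_genes=1500,
        n_core_up=80,
        n_core_down=80,
        n_tfr_shared=40,
        n_specific_per_condition=40,
    )


@pytest.fixture(scope="session")
def sc_run(small_sc_config):
    cells, meta, truth = synthetic.generate_singlecell_experiment(small_sc_config)
    return {"cells": cells, "meta": meta, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_calls(values: dict[str, int], universe: list[str]) -> pd.Series:
    """Directional call vector over a fixed universe (0 where unspecified)."""
    s = pd.Series(0, index=pd.Index(universe), dtype=int)
    for g, v in values.items():
        s[g] = v
    return s
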
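import numpy as np
import pandas as pd
import pytest

from qgdemar import (
    ConditionKey,
    ProbeMatrix,
    SimulationParams,
    SpikeSpec,
    simulate_factorial,
)


@pytest.fixture(scope="session")
def tiny_matrix() -> ProbeMatrix:
    """Hand-built 4-probe matrix: 2 strains x 2 phases x 2 replicates."""
    samples = {}
    meta_rows = []
    base = {"WT": 0.0, "M": 1.0}
    shift = {"exp": 0.0, "stat": 0.5}
    for strain in ("WT", "M"):
        for phase in ("exp", "stat"):
            for rep in (1, 2):
                name = f"{strain}_{phase}_r{rep}"
                samples[name] = [
                    4.0 + base[strain] + shift[phase],
                    6.0 + base[strain] + shift[phase],
                    8.0 + base[strain],
                    5.0 + base[strain] - shift[phase],
                ]
                meta_rows.append(
                    {"sample": name, "strain": strain, "phase": phase, "replicate": rep}
                )
    values = pd.DataFrame(samples, index=["p1", "p2", "p3", "p4"])
    genes = pd.Series(["gA", "gB", None, "gC"], index=values.index, name="gene")
    return ProbeMatrix(
        values=values, samples=pd.DataFrame(meta_rows).set_index("sample"), genes=genes
    )


@pytest.fixture(scope="session")
def spiked_simulation():
    """One medium simulation with 1% up / 0.5% down spikes, reused read-only."""
    params = SimulationParams(
        n_probes=10000,
        n_annotated=9000,
        strains=("WT", "M"),
        phases=("exponential", "chemostat"),
        replicates_per_condition=3,
        spike_specs=(SpikeSpec("M", "chemostat", 0.01, 0.005, 4.0),),
        seed=11,
    )
    return simulate_factorial(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


KEY_M_CHEMO = ConditionKey("M", "chemostat")
KEY_WT_CHEMO = ConditionKey("WT", "chemostat")
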
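from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pollenscreen.expr_model import ALL_TISSUES, ExpressionDataset, SampleDesign

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def dataset_from_tissue_values(
    tissue_values: dict[str, list[float]],
    n_replicates: int = 3,
    calls: str = "P",
) -> ExpressionDataset:
    """Dataset whose replicates are constant per tissue (exact medians)."""
    tissues = list(tissue_values)
    n_genes = len(next(iter(tissue_values.values())))
    design = SampleDesign(
        samples=tuple(
            (f"{t}_{r + 1}", t, r + 1) for t in tissues for r in range(n_replicates)
        )
    )
    genes = [f"g{i}" for i in range(n_genes)]
    data = {
        f"{t}_{r + 1}": np.asarray(tissue_values[t], dtype=float)
        for t in tissues
        for r in range(n_replicates)
    }
    intensity = pd.DataFrame(data, index=pd.Index(genes, name="probe_id"))
    call_df = pd.DataFrame(calls, index=intensity.index, columns=intensity.columns)
    return ExpressionDataset(intensity=intensity, calls=call_df, design=design)


def random_full_dataset(rng: np.random.Generator, n_genes: int = 50) -> ExpressionDataset:
    """Random positive dataset over the canonical 8-tissue x 3-rep design."""
    design = SampleDesign.default()
    intensity = pd.DataFrame(
        rng.lognormal(5.0, 1.0, size=(n_genes, len(design.sample_ids))),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="probe_id"),
        columns=design.sample_ids,
    )
    calls = pd.DataFrame("P", index=intensity.index, columns=intensity.columns)
    return ExpressionDataset(intensity=intensity, calls=calls, design=design)


@pytest.fixture(scope="session")
def default_sim():
    """One shared default-condition simulation (seed 11, 5000 genes)."""
    from pollenscreen.synthetic_data import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=11, n_genes=5000))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_tissues() -> list[str]:
    return list(ALL_TISSUES)
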
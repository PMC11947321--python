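"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import secretopanel as sp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_quant(
    values: np.ndarray | list,
    groups: list[tuple[str, int]],
    n_reps: int = 3,
    protein_ids: list[str] | None = None,
) -> sp.QuantMatrix:
    """Build a QuantMatrix from a proteins × runs array.

    Runs are ordered group-by-group, sample-by-sample, replicate-by-replicate;
    ``values`` must have one column per run (NaN = not identified).
    """
    run_names, sample_ids, group_labels, reps = [], [], [], []
    for g, n in groups:
        for s in range(1, n + 1):
            for r in range(1, n_reps + 1):
                run_names.append(f"{g}_s{s}_{r}")
                sample_ids.append(f"{g}_s{s}")
                group_labels.append(g)
                reps.append(r)
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i + 1}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"), columns=run_names)
    runs = pd.DataFrame(
        {"sample_id": sample_ids, "group": group_labels, "tech_rep": reps},
        index=pd.Index(run_names, name="run"),
    )
    return sp.QuantMatrix(values=frame, runs=runs)


def make_detection(
    detected: pd.DataFrame, sample_groups: pd.Series, value: float = 100.0
) -> sp.DetectionMatrix:
    """DetectionMatrix with a constant collapsed value wherever detected."""
    values = detected.astype(float) * value
    values = values.where(detected)
    return sp.DetectionMatrix(
        detected=detected, values=values, sample_groups=sample_groups
    )


@pytest.fixture(scope="session")
def default_dataset() -> sp.SimulatedDataset:
    """One study-sized synthetic experiment (2000 proteins, 5/4/6 design)."""
    return sp.simulate_dataset(sp.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset) -> sp.PipelineResult:
    return sp.run_pipeline(default_dataset.quant, default_dataset.localization)
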
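"""Shared fixtures: small designs, count tables, and graph factories."""

import numpy as np
import pandas as pd
import pytest

from sipaug.containers import CountTable
from sipaug.design import ExperimentDesign, KineticsParams


@pytest.fixture
def single_phase_design() -> ExperimentDesign:
    """One 8-day phase, one dose at day 0, dense measurements."""
    return ExperimentDesign(
        treatments=("sterilized", "non-Inoc"),
        dosing_days=(0.0,),
        phase_bounds={"I": (0.0, 8.0)},
        sampling_days=(0.0, 4.0, 8.0),
        measurement_days=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
        replicates=3,
        seed=0,
    )


@pytest.fixture
def noiseless() -> KineticsParams:
    return KineticsParams(k_abiotic=0.0, k_bio={}, noise_cv=0.0)


def make_table(counts: dict[str, list[int]], treatments: dict[str, str] | None = None,
               asv_ids: list[str] | None = None) -> CountTable:
    """Count table from a {sample: counts} dict with minimal metadata."""
    frame = pd.DataFrame(counts)
    frame.index = asv_ids or [f"ASV{i + 1}" for i in range(len(frame))]
    meta = pd.DataFrame(
        {
            "treatment": [
                (treatments or {}).get(s, "t1") for s in frame.columns
            ],
            "day": 0,
            "replicate": range(1, len(frame.columns) + 1),
        },
        index=frame.columns,
    )
    return CountTable(frame, meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
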
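import numpy as np
import pandas as pd
import pytest

from cutaneo import (
    CountTable,
    SampleMetadata,
    SimulationConfig,
    TaxonomyTable,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (51-triplet) default-effect cohort."""
    return simulate_cohort(SimulationConfig(cohort_seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down cohort for fast structural tests."""
    cfg = SimulationConfig(n_triplets=12, n_otus=60, n_genera=10, cohort_seed=11)
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_table():
    return CountTable(
        pd.DataFrame(
            [[5, 0], [3, 2], [0, 8]],
            index=["t1", "t2", "t3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def tiny_taxonomy():
    rows = {
        "t1": ["P1", "C1", "O1", "F1", "G1"],
        "t2": ["P1", "C1", "O1", "F1", "G1"],
        "t3": ["P2", "C2", "O2", "F2", "G2"],
    }
    return TaxonomyTable(
        pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["phylum", "class", "order", "family", "genus"],
        )
    )


def triplet_metadata(n_triplets: int, seed: int = 0) -> SampleMetadata:
    """Minimal valid triplet metadata for hand-built tables."""
    rows = {}
    for t in range(n_triplets):
        for st in ("control", "unaffected", "lesion"):
            rows[f"T{t:02d}.{st}"] = {
                "skin_type": st,
                "triplet_id": f"T{t:02d}",
                "subject_id": f"C_T{t:02d}" if st == "control" else f"P_T{t:02d}",
                "body_site": "body",
                "microenvironment": "dry",
            }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))
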
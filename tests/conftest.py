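import numpy as np
import pandas as pd
import pytest

from dysbiome import AsvTable, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest matched cohort with the default effect structure, shared
    across read-only tests."""
    config = CohortConfig(
        n_pairs={"F": 8, "MSM": 12, "MSW": 8},
        n_asvs=150,
        sequencing_depth_mean=6000,
        hiv_effect={**{i: 1.5 for i in range(10)}, **{i: -1.5 for i in range(10, 20)}},
        msm_effect={**{i: 1.2 for i in range(30, 50)}, **{i: 1.2 for i in range(10, 15)}},
        rai_effect={i: 1.0 for i in range(30, 40)},
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture()
def toy_table():
    """Hand-built 4-sample x 5-ASV table with known prevalences."""
    counts = pd.DataFrame(
        [[5, 0, 1, 0, 2],
         [3, 0, 0, 0, 1],
         [0, 0, 2, 7, 0],
         [1, 0, 0, 0, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c", "d", "e"],
    )
    return AsvTable(counts)


@pytest.fixture()
def paired_metadata():
    """Three matched pairs in one subgroup."""
    rows = []
    for i in range(1, 4):
        for status, suffix in (("PWH", "P"), ("SN", "N")):
            rows.append({
                "sample_id": f"s{i}{suffix}", "hiv_status": status, "subgroup": "MSM",
                "pair_id": f"pair{i}", "rai": "RAI-", "birth_country": "NL",
                "age": 50.0, "bmi": 24.0,
            })
    return pd.DataFrame(rows).set_index("sample_id")
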
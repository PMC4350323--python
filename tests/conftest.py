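import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pasdrift as pdr

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_collection() -> pdr.PathwayCollection:
    """Two small pathways over a shared 5-gene universe."""
    return pdr.PathwayCollection(
        pathways=[
            pdr.PathwayDefinition(
                "p1", "growth", {"gA": 1.0, "gB": -1.0, "gC": 0.5}
            ),
            pdr.PathwayDefinition(
                "p2", "repair", {"gC": 1.0, "gD": -0.5, "gE": 0.0}
            ),
        ],
        collection_name="toy",
    )


@pytest.fixture(scope="session")
def aging_bundle() -> pdr.StudyBundle:
    return pdr.make_paper_like_study("aging4", seed=1)


@pytest.fixture(scope="session")
def aging_pas(aging_bundle) -> pdr.PASMatrix:
    return pdr.compute_pas_matrix(
        aging_bundle.matrices,
        aging_bundle.groups,
        aging_bundle.collection,
        aging_bundle.reference,
    )


@pytest.fixture(scope="session")
def senescence_bundle() -> pdr.StudyBundle:
    return pdr.make_paper_like_study("senescence", seed=3)


def make_pas_matrix(values: pd.DataFrame, groups: dict[str, list[str]]) -> pdr.PASMatrix:
    """Assemble a PASMatrix directly from a pathway x sample frame."""
    sample_groups = pd.Series(
        {s: g for g, samples in groups.items() for s in samples}
    ).reindex(values.columns)
    sample_datasets = pd.Series("ds1", index=values.columns)
    return pdr.PASMatrix(
        values=values,
        sample_groups=sample_groups,
        sample_datasets=sample_datasets,
        mode="filtered",
    )
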
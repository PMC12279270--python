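import numpy as np
import pandas as pd
import pytest

from micromet import AnalysisConfig
from micromet.io import (
    BiomassSeries,
    CohortDesign,
    FeatureTable,
    TaxonomyTable,
)
from micromet.simulate import PlantedEdge, SimulationConfig, generate_cohort


@pytest.fixture
def tiny_counts():
    data = pd.DataFrame(
        [[5, 0, 10], [3, 7, 0], [2, 3, 10]],
        index=["asv1", "asv2", "asv3"],
        columns=["s1", "s2", "s3"],
    )
    return FeatureTable(data, "asv_counts")


@pytest.fixture
def tiny_taxonomy():
    rows = {
        "asv1": ["Bacteria", "Firmicutes", "c", "o", "Lachnospiraceae", "g1"],
        "asv2": ["Bacteria", "Firmicutes", "c", "o", "Lachnospiraceae", "g1"],
        "asv3": ["Bacteria", "Bacteroidota", "c", "o", "Bacteroidaceae", ""],
    }
    return TaxonomyTable(
        pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["kingdom", "phylum", "class", "order", "family", "genus"],
        )
    )


@pytest.fixture
def tiny_biomass():
    return BiomassSeries(pd.Series([1e9, 2e9, 5e8], index=["s1", "s2", "s3"]))


@pytest.fixture
def tiny_design():
    return CohortDesign(
        pd.DataFrame({"group": ["HC", "CD", "UC"]}, index=["s1", "s2", "s3"])
    )


@pytest.fixture(scope="session")
def planted_bundle():
    """One simulated cohort with a strong planted HC edge (two driver strains)."""
    cfg = SimulationConfig(
        planted_edges=[PlantedEdge("g001", "m001", "HC", 0.8)],
        drivers_per_edge=2,
        rng_seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def default_cfg():
    return AnalysisConfig()
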
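import numpy as np
import pandas as pd
import pytest

from changevec import (ComparisonDesign, DesignEntry, FeatureTable,
                       SampleMetadata, TaxonomyMap)


@pytest.fixture
def small_table() -> FeatureTable:
    data = pd.DataFrame(
        [[2.0, 1.0, 0.0, 5.0],
         [2.0, 3.0, 0.0, 5.0],
         [0.0, 0.0, 4.0, 0.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(data)


@pytest.fixture
def taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        "f1": ("Bacteria", "A", "C1"),
        "f2": ("Bacteria", "A", "C2"),
        "f3": ("Bacteria", "B"),
    })


@pytest.fixture
def metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {"system": ["sys1"] * 4,
         "population": ["benthic_A", "limnetic_A", "benthic_B", "limnetic_B"],
         "ecotype": ["benthic", "limnetic", "benthic", "limnetic"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample-id"),
    )
    return SampleMetadata(df)


@pytest.fixture
def pair_design_2() -> ComparisonDesign:
    return ComparisonDesign(kind="pair", entries=[
        DesignEntry("v1", "benthic_A", "limnetic_A"),
        DesignEntry("v2", "benthic_B", "limnetic_B"),
    ])
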
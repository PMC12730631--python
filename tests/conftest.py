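import numpy as np
import pandas as pd
import pytest

from zoocomm.data_io import CommunityDataset, validate_traits
from zoocomm.synthetic_data import generate_community, generate_traits, qinhuangdao_preset


@pytest.fixture
def toy_records() -> pd.DataFrame:
    # 2 samples x 2 species, one implicit zero (s2 lacks spB)
    return pd.DataFrame(
        [
            {"sample_id": "s1", "stratum": "E1", "season": "Mar", "species_id": "spA", "n": 50, "v": 2.5},
            {"sample_id": "s1", "stratum": "E1", "season": "Mar", "species_id": "spB", "n": 10, "v": 2.5},
            {"sample_id": "s2", "stratum": "E1", "season": "Jun", "species_id": "spA", "n": 0, "v": 1.0},
        ]
    )


@pytest.fixture
def toy_dataset(toy_records) -> CommunityDataset:
    return CommunityDataset(records=toy_records)


@pytest.fixture
def toy_community_file(tmp_path, toy_records):
    path = tmp_path / "community.csv"
    toy_records.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_traits() -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"species_id": "spA", "taxon_class": "copepod_cladoceran", "body_size_mm": 2.0, "feeding_habit": "filter", "notes": ""},
            {"species_id": "spB", "taxon_class": "rotifer", "body_size_mm": np.nan, "feeding_habit": "carnivore", "notes": ""},
        ]
    )
    return validate_traits(df)


@pytest.fixture(scope="session")
def preset_scenario():
    return qinhuangdao_preset(seed=7)


@pytest.fixture(scope="session")
def preset_traits(preset_scenario):
    return generate_traits(preset_scenario)


@pytest.fixture(scope="session")
def preset_dataset(preset_scenario, preset_traits):
    return generate_community(preset_scenario, preset_traits)
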
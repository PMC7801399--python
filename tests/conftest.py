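import numpy as np
import pandas as pd
import pytest

from anxmediate import synthdata


@pytest.fixture(scope="session")
def small_spec() -> synthdata.CohortSpec:
    """Desk-scale cohort spec: full strain panel, reduced marker/OTU counts."""
    return synthdata.CohortSpec(
        n_strains=30,
        mice_per_strain=(7, 25),
        n_snps=4000,
        n_taxa_families=30,
        n_otus=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec) -> synthdata.Cohort:
    return synthdata.gen_cohort(small_spec)


@pytest.fixture(scope="session")
def small_phenotypes(small_cohort) -> pd.DataFrame:
    from anxmediate import behavior

    rows = {}
    for mid, prof in small_cohort.profiles():
        rows[mid] = behavior.extract_phenotypes(prof).as_array()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(behavior.PHENOTYPE_NAMES))
    df.index.name = "mouse_id"
    return df.join(small_cohort.mice.set_index("mouse_id")[["strain", "sex", "cage"]])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
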
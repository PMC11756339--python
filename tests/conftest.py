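import numpy as np
import pandas as pd
import pytest

from morphlands import (
    GridSpec,
    SyntheticConfig,
    TraitSchema,
    TraitTable,
    generate_dataset,
)


def make_trait_table(rows, kinds):
    """Build a TraitTable from a list of row dicts (keys: specimen_id, species,
    locomotor, dietary, family, then trait values)."""
    df = pd.DataFrame(rows).set_index("specimen_id")
    meta = df[["species", "locomotor", "dietary", "family"]]
    traits = df[list(kinds)]
    return TraitTable(traits=traits, meta=meta, schema=TraitSchema(kinds=dict(kinds)))


@pytest.fixture
def small_table():
    """Three specimens, three linear traits and one angle."""
    kinds = {"a": "linear", "b": "linear", "c": "linear", "theta": "angular"}
    rows = [
        dict(specimen_id="s1", species="sp1", locomotor="cursorial", dietary="omnivory",
             family="Canidae", a=2.0, b=8.0, c=4.0, theta=45.0),
        dict(specimen_id="s2", species="sp2", locomotor="arboreal", dietary="omnivory",
             family="Felidae", a=3.0, b=3.0, c=3.0, theta=90.0),
        dict(specimen_id="s3", species="sp3", locomotor="cursorial", dietary="herbivory",
             family="Canidae", a=1.0, b=4.0, c=16.0, theta=180.0),
    ]
    return make_trait_table(rows, kinds)


@pytest.fixture(scope="session")
def full_scale_dataset():
    """Default-sized synthetic dataset: 109 species x 136 traits."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset used where full size is unnecessary."""
    return generate_dataset(SyntheticConfig(n_species=42, n_traits=40, n_angular=8, seed=7))


@pytest.fixture
def unit_grid():
    return GridSpec(0.0, 1.0, 0.0, 1.0, nx=21, ny=21)
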
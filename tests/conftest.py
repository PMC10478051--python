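import pandas as pd
import pytest

from foodenv import indices, synth, taxonomy


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(n_rows=5, n_cols=5, years=(2000, 2004), seed=11)


@pytest.fixture(scope="session")
def small_geoms(small_config):
    return synth.generate_lattice(small_config)


@pytest.fixture(scope="session")
def small_attrs(small_config, small_geoms):
    return synth.generate_attributes(small_config, small_geoms)


@pytest.fixture(scope="session")
def small_establishments(small_config, small_attrs):
    return synth.generate_establishments(small_config, small_attrs)


@pytest.fixture(scope="session")
def small_classified(small_establishments):
    return taxonomy.classify_frame(small_establishments)


@pytest.fixture(scope="session")
def small_panel(small_config, small_classified, small_geoms):
    return indices.build_panel(
        small_classified,
        small_config.year_list,
        tract_ids=[g.tract_id for g in small_geoms],
    )


@pytest.fixture(scope="session")
def small_joined(small_panel, small_attrs):
    from foodenv import ppml

    return ppml.join_panel(small_panel, small_attrs)


@pytest.fixture()
def toy_establishments():
    """Hand-written registry with known counts for tract A, year 2000:
    2 healthy (grocery >=5 employees, supercentre), 1 intermediate
    (full-service), 2 unhealthy (convenience-coded + reclassified small
    grocery) and 1 out-of-scope record."""
    return pd.DataFrame(
        [
            ("e1", "A", 2000, "445110", "Big Grocery", 25, 1000.0),
            ("e2", "A", 2000, "452311", "MegaCentre", 120, 3000.0),
            ("e3", "A", 2000, "722511", "Diner", 12, 500.0),
            ("e4", "A", 2000, "445120", "QuickStop", 3, 250.0),
            ("e5", "A", 2000, "445110", "Tiny Grocery", 2, 100.0),
            ("e6", "A", 2000, "531120", "Lessor", 4, 800.0),
            ("e7", "B", 2001, "722513", "Burger Barn", 9, 400.0),
        ],
        columns=["establishment_id", "tract_id", "year", "naics", "name", "employees", "sales"],
    )
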
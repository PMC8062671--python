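import dataclasses

import pytest

from firestats.catalog import FireCatalog, FireRecord
from firestats.synthetic import california_like, gen_catalog, gen_covariate_stack


def make_record(i=0, **kw):
    defaults = dict(
        id=f"R{i:04d}", x=1000.0 * i, y=500.0 * i, year=2005, month=7,
        size_acres=100.0, cause="lightning", fuel="timber",
    )
    defaults.update(kw)
    return FireRecord(**defaults)


@pytest.fixture
def toy_catalog():
    """Six records spanning two decades, mixed causes and sizes."""
    recs = [
        make_record(0, year=2001, month=6, size_acres=15.0, cause="lightning"),
        make_record(1, year=2001, month=7, size_acres=650.0, cause="powerline"),
        make_record(2, year=2003, month=7, size_acres=40.0, cause="vehicle", fuel="brush"),
        make_record(3, year=2010, month=8, size_acres=500.0, cause="campfire"),
        make_record(4, year=2015, month=9, size_acres=5000.0, cause="lightning"),
        make_record(5, year=2019, month=2, size_acres=12.0, cause="unknown", fuel=None),
    ]
    return FireCatalog.from_records(recs)


@pytest.fixture(scope="session")
def canonical_catalog():
    """The packaged scenario at one fixed seed (session-cached)."""
    return gen_catalog(california_like(seed=11))


@pytest.fixture(scope="session")
def small_scenario():
    """Downscaled variant of the packaged scenario for fast pipeline runs."""
    cfg = california_like(seed=5)
    fields = {k: dict(v) for k, v in cfg.covariate_fields.items()}
    return dataclasses.replace(cfg, n_fires=600, stack_cell_size=9000.0, covariate_fields=fields)


@pytest.fixture(scope="session")
def canonical_stack(small_scenario):
    return gen_covariate_stack(small_scenario)
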
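import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_records(rows):
    """Build a record DataFrame from (ring, species, site, year, visit, age) tuples."""
    return pd.DataFrame(
        rows, columns=["ring_id", "species_code", "site_id", "year", "visit", "age_class"]
    )


@pytest.fixture
def records_csv(tmp_path):
    """Write record rows to a CSV and return its path."""

    def _write(rows, name="records.csv", header=None):
        path = tmp_path / name
        df = make_records(rows)
        if header:
            df.columns = header
        df.to_csv(path, index=False)
        return path

    return _write


def random_fixture(rng, n_records=200, n_sites=6, n_species=3, years=(2004, 2009)):
    """A random record table plus a random effort table, for filter oracles."""
    lo, hi = years
    rows = []
    for i in range(n_records):
        rows.append(
            (
                f"R{rng.integers(0, n_records // 2):04d}",
                f"SP{rng.integers(1, n_species + 1):02d}",
                f"ST{rng.integers(1, n_sites + 1):02d}",
                int(rng.integers(lo, hi + 1)),
                int(rng.integers(1, 11)),
                "adult" if rng.random() < 0.5 else "juvenile",
            )
        )
    records = make_records(rows)
    effort = pd.DataFrame(
        [
            (f"ST{s:02d}", y, int(rng.integers(4, 13)))
            for s in range(1, n_sites + 1)
            for y in range(lo, hi + 1)
        ],
        columns=["site_id", "year", "n_visits"],
    )
    return records, effort
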
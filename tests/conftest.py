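import numpy as np
import pandas as pd
import pytest

from fishstab.dataio import LONG_COLUMNS, MonthlyPanel


def make_records(rows):
    """Long-format frame from (region, year, month, species, kind, value) tuples."""
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


@pytest.fixture
def two_species_panel():
    """The worked 2x2 example: A=[4,6], B=[5,4]."""
    return MonthlyPanel("MD", 2010, "harvest_kg", ("A", "B"), (1, 2),
                        np.array([[4.0, 6.0], [5.0, 4.0]]))


@pytest.fixture
def lognormal_panels():
    """Seeded ensemble of random lognormal panels, n in 2..6, T=5."""
    rng = np.random.default_rng(20240917)
    panels = []
    for n in range(2, 7):
        panels.extend(rng.lognormal(0.0, 1.0, size=(400, n, 5)))
    return panels
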
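import pandas as pd
import pytest


def make_raw_table(rows):
    """Build a RawAssayTable from (experiment, cell_type, particle, dose,
    endpoint, role, replicate, signal) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id", "cell_type", "particle", "dose", "endpoint",
            "role", "replicate", "signal",
        ],
    )


@pytest.fixture
def simple_raw():
    """One experiment, one endpoint: controls {100, 110, 90} and a dosed well."""
    rows = [
        ("E1", "A549", "NP", 0.0, "ATP", "cells", 1, 100.0),
        ("E1", "A549", "NP", 0.0, "ATP", "cells", 2, 110.0),
        ("E1", "A549", "NP", 0.0, "ATP", "cells", 3, 90.0),
        ("E1", "A549", "NP", 10.0, "ATP", "cells", 1, 50.0),
    ]
    return make_raw_table(rows)


@pytest.fixture
def two_experiment_raw():
    """Two experiments with control means 100 and 200, each a dosed well of 80."""
    rows = [
        ("E1", "A549", "NP", 0.0, "ATP", "cells", 1, 100.0),
        ("E1", "A549", "NP", 10.0, "ATP", "cells", 1, 80.0),
        ("E2", "A549", "NP", 0.0, "ATP", "cells", 1, 200.0),
        ("E2", "A549", "NP", 10.0, "ATP", "cells", 1, 80.0),
    ]
    return make_raw_table(rows)
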
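import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_anova_frame():
    """Balanced 3 accessions x 2 blocks with hand-checkable sums of squares."""
    return pd.DataFrame(
        {
            "accession_id": ["A", "A", "B", "B", "C", "C"],
            "year": ["Y1"] * 6,
            "block": [1, 2, 1, 2, 1, 2],
            "pct60": [0.0] * 6,
            "pct100": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
        }
    )


@pytest.fixture
def balanced_random_frame():
    """Balanced 8 accessions x 3 years x 2 blocks with seeded noise."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(8):
        for y in ("Y1", "Y2", "Y3"):
            for b in (1, 2):
                rows.append(
                    {
                        "accession_id": f"A{i}",
                        "year": y,
                        "block": b,
                        "pct60": float(rng.choice([0, 25, 50, 75, 100])),
                        "pct100": float(rng.choice([0, 25, 50, 75, 100])),
                    }
                )
    return pd.DataFrame(rows)
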
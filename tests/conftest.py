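import numpy as np
import pandas as pd
import pytest

from pollenheat.trial_data import make_panel


def build_records(rows):
    return pd.DataFrame(
        rows, columns=["genotype", "season", "treatment", "replicate", "viability"]
    )


@pytest.fixture
def toy_panel():
    """2 genotypes x 2 seasons x 2 treatments x 1 replicate, hand-written."""
    rows = [
        ("A", "S1", "normal", 1, 90.0),
        ("A", "S1", "stress", 1, 80.0),
        ("B", "S1", "normal", 1, 100.0),
        ("B", "S1", "stress", 1, 90.0),
        ("A", "S2", "normal", 1, 92.0),
        ("A", "S2", "stress", 1, 85.0),
        ("B", "S2", "normal", 1, 96.0),
        ("B", "S2", "stress", 1, 88.0),
    ]
    return make_panel(build_records(rows))


@pytest.fixture
def random_panel_factory():
    """Balanced random panels with arbitrary dimensions, plain-numpy built."""

    def build(G=4, S=2, T=2, r=3, seed=0, low=50.0, high=100.0):
        rng = np.random.default_rng(seed)
        rows = []
        treatments = ["normal", "stress"][:T]
        for gi in range(G):
            for si in range(S):
                for t in treatments:
                    for ri in range(r):
                        rows.append(
                            (
                                f"g{gi}",
                                f"s{si}",
                                t,
                                ri + 1,
                                float(rng.uniform(low, high)),
                            )
                        )
        return make_panel(build_records(rows))

    return build
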
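import numpy as np
import pandas as pd
import pytest

from asimm.growth import ReactorParameters
from asimm.io import CountTable
from asimm.simulate import simulate_experiment


@pytest.fixture(scope="session")
def params():
    return ReactorParameters()


@pytest.fixture
def toy_table():
    return CountTable(
        pd.DataFrame(
            {"s1": [0, 5, 10], "s2": [3, 0, 7]},
            index=["f1", "f2", "f3"],
        )
    )


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated reactor set, shared across tests (seed 0)."""
    return simulate_experiment(seed=0)


def make_set_metadata(set_id="A", n_blocks=3, n_reps=3, phase="P2F"):
    """27-reactor metadata frame for classification toy tests."""
    rows = []
    feeds = ["syntho_only", "active_solids", "autoclaved_solids"]
    for b in "abc"[:n_blocks]:
        for feed in feeds:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{set_id}-{b}{rep}-{feed[:3]}",
                        "set": set_id,
                        "block": b,
                        "feed": feed,
                        "phase": phase,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def meta27():
    return make_set_metadata()


def relab_frame(meta, values: dict):
    """Genus x sample relative-abundance frame from {genus: {feed: value}}."""
    data = {}
    for sid in meta.index:
        feed = meta.loc[sid, "feed"]
        data[sid] = {g: spec.get(feed, 0.0) for g, spec in values.items()}
    return pd.DataFrame(data)
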
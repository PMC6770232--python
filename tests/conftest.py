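import numpy as np
import pandas as pd
import pytest

from refstab import CtTable, QuantityTable, SampleSheet


@pytest.fixture
def small_ct() -> CtTable:
    """3 genes × 4 samples, hand-entered values."""
    frame = pd.DataFrame(
        {
            "s1": [20.0, 25.0, 18.0],
            "s2": [21.0, 24.5, 18.5],
            "s3": [20.5, 25.5, 17.5],
            "s4": [19.5, 24.0, 18.2],
        },
        index=["gA", "gB", "gC"],
    )
    return CtTable(frame)


@pytest.fixture
def triplicate_experiment() -> tuple[CtTable, SampleSheet]:
    """2 conditions × 2 bio reps × 3 tech reps for aggregation tests."""
    rng = np.random.default_rng(7)
    columns = {}
    rows = []
    for condition in ("ctrl", "heat"):
        for b in (1, 2):
            base = rng.uniform(18, 26, size=3)
            for t in (1, 2, 3):
                sid = f"{condition}:b{b}:t{t}"
                columns[sid] = base + rng.normal(0, 0.1, size=3)
                rows.append(
                    {
                        "sample_id": sid,
                        "condition": condition,
                        "bio_rep": b,
                        "tech_rep": t,
                        "group": condition,
                    }
                )
    ct = CtTable(pd.DataFrame(columns, index=["gA", "gB", "gC"]))
    sheet = SampleSheet(pd.DataFrame(rows))
    return ct, sheet


@pytest.fixture
def random_quantities() -> QuantityTable:
    """5 genes × 8 samples of lognormal quantities."""
    rng = np.random.default_rng(11)
    q = rng.lognormal(0.0, 0.5, size=(5, 8))
    return QuantityTable(
        pd.DataFrame(
            q,
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(8)],
        )
    )
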
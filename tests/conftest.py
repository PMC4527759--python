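import numpy as np
import pytest

from nemalife.records import (
    LifeTable,
    LifeTableRow,
    ObservationSchedule,
    load_pacificus_life_table,
)


@pytest.fixture(scope="session")
def pacificus_table() -> LifeTable:
    return load_pacificus_life_table()


def random_life_table(
    rng: np.random.Generator,
    min_rows: int = 5,
    max_rows: int = 13,
    ensure_growing: bool = False,
) -> LifeTable:
    """Random but valid cohort life table with integer-hour checkpoints
    (so a 1 h Leslie grid resolves every age exactly)."""
    n0 = int(rng.integers(20, 60))
    k = int(rng.integers(min_rows, max_rows + 1))
    widths = rng.choice([6, 12, 24], size=k)
    start = int(rng.integers(1, 13)) * 6
    times = start + np.cumsum(widths)
    alive = n0 - np.cumsum(rng.integers(0, 3, size=k))
    alive = np.maximum(alive, 1)
    alive = np.minimum.accumulate(alive)
    mx = rng.gamma(1.5, 2.0, size=k)
    mx[rng.random(k) < 0.2] = 0.0
    if mx.sum() == 0 or ensure_growing:
        mx[int(rng.integers(0, k))] += 1.0
    if ensure_growing:
        lxmx = (alive / n0) * mx
        mx *= (1.5 + rng.random() * 3.0) / lxmx.sum()
    rows = tuple(
        LifeTableRow(
            time_x=float(t), width_d=float(w), lx=float(a) / n0, mx=float(m)
        )
        for t, w, a, m in zip(times, widths, alive, mx)
    )
    return LifeTable(rows=rows, n0=n0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def schedule_6h() -> ObservationSchedule:
    # 6 h cadence with checkpoints at 9, 15, ..., matching the published
    # mid-interval offsets (an egg at 100 h falls in (99, 105])
    return ObservationSchedule.from_breaks([3.0 + 6 * i for i in range(60)])
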
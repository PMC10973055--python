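import random

import pytest

from splitaudit import synthetic
from splitaudit.config import DatasetConfig, SplitAssignment, Surgery


@pytest.fixture
def toy_config():
    return DatasetConfig(
        name="toy",
        phases=("P1", "P2", "P3", "P4"),
        instruments=("A", "B", "C"),
        phase_fps=1,
        instrument_fps=1,
        split=SplitAssignment.from_lists(train=["s1", "s2"], val=[], test=["s3"]),
    )


def make_surgery(sid, phases=None, instruments=None):
    n = len(phases) if phases is not None else len(instruments)
    return Surgery(
        surgery_id=sid,
        frame_indices=tuple(range(n)),
        phases=tuple(phases) if phases is not None else None,
        instruments=tuple(tuple(v) for v in instruments) if instruments else None,
    )


@pytest.fixture
def toy_surgeries():
    # s1/s2 train, s3 test; instruments in config order (A, B, C)
    return [
        make_surgery(
            "s1",
            phases=["P1", "P1", "P2", "P3", "P4"],
            instruments=[(1, 0, 0), (1, 1, 0), (0, 0, 0), (0, 1, 0), (1, 1, 1)],
        ),
        make_surgery(
            "s2",
            phases=["P2", "P3", "P2", "P4"],
            instruments=[(0, 1, 0), (1, 0, 0), (1, 1, 0), (0, 0, 1)],
        ),
        make_surgery(
            "s3",
            phases=["P1", "P2", "P3", "P4"],
            instruments=[(1, 0, 0), (0, 0, 0), (1, 1, 0), (0, 1, 1)],
        ),
    ]


@pytest.fixture
def dense_dataset():
    return synthetic.generate_dataset(synthetic.dense_spec(seed=7))


def random_spec(rng: random.Random) -> synthetic.GeneratorSpec:
    """A small random generator spec within the acceptance envelope."""
    n_phases = rng.randint(3, 8)
    n_instruments = rng.randint(2, 5)
    n_surgeries = rng.randint(4, 20)
    mean = tuple(rng.uniform(2.0, 10.0) for _ in range(n_phases))
    quirks = []
    if rng.random() < 0.4 and n_phases >= 3:
        quirks.append(synthetic.Quirk("skip_first", 1, rng.uniform(0.1, 0.4)))
    if rng.random() < 0.3:
        quirks.append(
            synthetic.Quirk("end_in", rng.randrange(n_phases - 1), rng.uniform(0.1, 0.3))
        )
    if rng.random() < 0.5:
        mode = dict(
            instrument_mode="bernoulli",
            instrument_probs=tuple(
                tuple(rng.uniform(0.05, 0.6) for _ in range(n_instruments))
                for _ in range(n_phases)
            ),
        )
    else:
        combos = [(), *((i,) for i in range(n_instruments))]
        if n_instruments >= 2:
            combos.append((0, 1))
        if n_instruments >= 3:
            combos.append((0, 1, 2))
        weights = [rng.uniform(0.2, 1.0) for _ in combos]
        total = sum(weights)
        mode = dict(
            instrument_mode="pool",
            combo_pool=tuple((c, w / total) for c, w in zip(combos, weights)),
        )
    return synthetic.GeneratorSpec(
        n_phases=n_phases,
        n_instruments=n_instruments,
        n_surgeries=n_surgeries,
        seed=rng.randrange(10**6),
        mean_run_length=mean,
        persistence=rng.choice([0.0, 0.0, 0.5]),
        quirks=tuple(quirks),
        **mode,
    )
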
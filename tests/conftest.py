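import numpy as np
import pytest

from dysmap.records import StimulationRecord
from dysmap.volumes import make_grid


@pytest.fixture
def small_grid():
    return make_grid((12, 12, 12), 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(n_subjects, per_subject, rng, extent=20.0, behaviour="b", p=0.4):
    """Random records on [0, extent]^3 with iid Bernoulli flags."""
    records = []
    for s in range(n_subjects):
        for _ in range(per_subject):
            records.append(
                StimulationRecord(
                    subject_id=f"s{s:03d}",
                    world_mm=tuple(rng.uniform(0, extent, 3)),
                    behaviours={behaviour: int(rng.uniform() < p)},
                )
            )
    # guard against a constant behaviour column in small draws
    flags = [r.flag(behaviour) for r in records]
    if len(set(flags)) == 1:
        r0 = records[0]
        records[0] = StimulationRecord(
            r0.subject_id, r0.world_mm, {behaviour: 1 - flags[0]}
        )
    return records


@pytest.fixture
def toy_records(rng):
    return make_records(4, 6, rng)
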
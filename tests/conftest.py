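import numpy as np
import pytest

import taumap as tm


@pytest.fixture(scope="session")
def planted_field():
    """Study-condition particle field: 100 micrographs x 20 pairs at 168 A."""
    cfg = tm.FieldSimConfig(seed=11)
    tableA, tableB, truth = tm.gen_particle_fields(cfg)
    return cfg, tableA, tableB, truth


@pytest.fixture(scope="session")
def planted_pairs(planted_field):
    _, tableA, tableB, _ = planted_field
    return tm.pair_particles(tableA, tableB).pairs


@pytest.fixture(scope="session")
def ab_dwells():
    """10^4 continuous dwells from the two-component A/B-construct model."""
    cfg = tm.DwellSimConfig(
        n_dwells=10_000, lifetimes=(1.2, 49.0), weights=(0.615, 0.385),
        frame_time=None, seed=23,
    )
    return tm.gen_dwells(cfg)


@pytest.fixture(scope="session")
def trnahis():
    return tm.annotate_trnahis()


def greedy_oracle(xyA, xyB, idsA, idsB, max_distance=None):
    """Reference pairing: repeatedly select the global minimum-distance pair.

    Literal restatement of the iterative nearest-neighbor procedure,
    independent of the sorted-sweep implementation.
    """
    remaining_a = list(range(len(xyA)))
    remaining_b = list(range(len(xyB)))
    out = []
    while remaining_a and remaining_b:
        best = None
        for i in remaining_a:
            for j in remaining_b:
                d = float(np.hypot(*(np.asarray(xyA[i]) - np.asarray(xyB[j]))))
                key = (d, idsA[i], idsB[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        if max_distance is not None and d > max_distance:
            break
        out.append((i, j, d))
        remaining_a.remove(i)
        remaining_b.remove(j)
    return out
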
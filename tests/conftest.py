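import numpy as np
import pytest

from fediv import (
    SpeciesRecord,
    TraitDefinition,
    TraitSchema,
    build_entities,
    default_fine_schema,
)


@pytest.fixture(scope="session")
def fine_schema():
    return default_fine_schema()


@pytest.fixture(scope="session")
def small_schema():
    """Three traits (one ordered), 3*2*2 = 12 combinations."""
    return TraitSchema(
        (
            TraitDefinition("size", ("a", "b", "c"), ordered=True,
                            collapse_map={"a": "lo", "b": "lo", "c": "hi"}),
            TraitDefinition("diet", ("x", "y"),
                            collapse_map={"x": "x", "y": "y"}),
            TraitDefinition("home", ("p", "q"),
                            collapse_map={"p": "one", "q": "one"}),
        )
    )


def make_records(tuples_with_occ, prefix="sp"):
    """Helper: [(trait_tuple, occupancy set), ...] -> SpeciesRecord list."""
    return [
        SpeciesRecord(f"{prefix}{i:03d}", tuple(tup), frozenset(occ))
        for i, (tup, occ) in enumerate(tuples_with_occ)
    ]


@pytest.fixture
def small_entities(small_schema):
    """10 species in 5 entities, pooled occupancy (5, 2, 1, 1, 1)."""
    rows = (
        [(("a", "x", "p"), {"A", "B"})] * 5
        + [(("b", "x", "p"), {"A"})] * 2
        + [(("c", "x", "p"), {"A"})]
        + [(("a", "y", "p"), {"B"})]
        + [(("c", "y", "q"), {"A", "B"})]
    )
    return build_entities(make_records(rows), small_schema, assemblages=("A", "B"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def random_occupancy(rng, max_fe=40, max_extra=200):
    fe = int(rng.integers(1, max_fe))
    extra = int(rng.integers(0, max_extra))
    return 1 + rng.multinomial(extra, np.full(fe, 1 / fe))
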
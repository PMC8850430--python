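import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run-to-run
settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from urinopept.proteome import build_database
from urinopept.synth import (
    SynthConfig,
    load_reference_catalogue,
    make_toy_proteomes,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def reference_catalogue():
    """The packaged catalogue of printed urinary wheat peptide forms."""
    return load_reference_catalogue()


@pytest.fixture(scope="session")
def toy_proteomes():
    return make_toy_proteomes(0)


@pytest.fixture(scope="session")
def wheat_db(toy_proteomes):
    return build_database(curated_records=toy_proteomes["wheat"])


@pytest.fixture(scope="session")
def human_db(toy_proteomes):
    return build_database(curated_records=toy_proteomes["human"], keywords=())


@pytest.fixture(scope="session")
def grain_dbs(toy_proteomes):
    return {
        species: build_database(curated_records=toy_proteomes[species])
        for species in ("wheat", "barley", "rye")
    }


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic default-condition cohort, shared across tests."""
    return simulate_cohort(SynthConfig(seed=11))


def brute_force_envelope(formula: dict[str, int]) -> dict[int, float]:
    """Exhaustive isotopologue enumeration, binned by neutron excess.

    Independent of the convolution implementation: enumerates, per element,
    every way of distributing the atoms over the element's isotopes
    (multinomial weights), then crosses elements. Exact for any molecule
    small enough to enumerate (tractable well beyond 60 atoms).
    """
    import itertools
    import math

    from urinopept._constants import ISOTOPES

    per_element: list[dict[int, float]] = []
    for el, n in formula.items():
        isotopes = ISOTOPES[el]
        k = len(isotopes)
        dist: dict[int, float] = {}
        for counts in itertools.product(range(n + 1), repeat=k - 1):
            rest = n - sum(counts)
            if rest < 0:
                continue
            full = (rest,) + counts
            coef = math.factorial(n)
            prob = 1.0
            for c, (mass_i, ab) in zip(full, isotopes):
                coef //= math.factorial(c)
                prob *= ab**c
            offset = sum(
                c * round(mass_i - isotopes[0][0]) for c, (mass_i, _) in zip(full, isotopes)
            )
            dist[offset] = dist.get(offset, 0.0) + coef * prob
        per_element.append(dist)
    total = {0: 1.0}
    for dist in per_element:
        nxt: dict[int, float] = {}
        for k1, p1 in total.items():
            for k2, p2 in dist.items():
                nxt[k1 + k2] = nxt.get(k1 + k2, 0.0) + p1 * p2
        total = nxt
    return total
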
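import numpy as np
import pytest

from layercascade import (
    SolverOptions,
    SyntheticSpec,
    birth_death_model,
    controller_model,
    generate_network,
)

#: Fast grid for unit tests; identities are asserted against tolerances
#: derived from these solver settings, not against hard-coded magic numbers.
FAST = SolverOptions(n_grid=201)
HORIZON = 3.0


def identity_tol(opts: SolverOptions, scale: float) -> float:
    """Agreement tolerance for trajectory identities: 10x solver tolerance."""
    return 10.0 * (opts.rtol * max(scale, 1.0) + opts.atol)


def corpus_specs(n: int = 25) -> list[SyntheticSpec]:
    """Seeded random-network corpus: <= 8 species, <= 12 reactions,
    2-4 functionalities, with and without overlap."""
    specs = []
    for s in range(n):
        specs.append(
            SyntheticSpec(
                n_species=5 + s % 4,
                n_reactions=8 + s % 5,
                n_functionalities=2 + s % 3,
                overlap_fraction=0.0 if s % 2 == 0 else 0.3,
                seed=s,
            )
        )
    return specs


@pytest.fixture(scope="session")
def fast_opts():
    return FAST


@pytest.fixture()
def birth_death():
    return birth_death_model()


@pytest.fixture(scope="session")
def controller():
    return controller_model()


@pytest.fixture(scope="session")
def small_random():
    """One fixed random network with overlap, reused across unit tests."""
    return generate_network(
        SyntheticSpec(n_species=6, n_reactions=9, n_functionalities=3,
                      overlap_fraction=0.25, seed=11)
    )


def max_abs(a: np.ndarray) -> float:
    return float(np.nanmax(np.abs(a)))
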
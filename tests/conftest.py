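import logging

import pytest

from rnaunrank import (
    StructureSampler,
    build_tables,
    enumerate_language,
    grammar_to_spec,
    load_builtin,
)

logging.getLogger("rnaunrank").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gsto():
    """The bundled 54-rule structure-motif SCFG with exact probabilities."""
    return load_builtin("Gsto_hat")


@pytest.fixture(scope="session")
def star_rational():
    """The normal-form grammar with published 4-decimal weights."""
    return load_builtin("Gsto_hat_star_rational")


@pytest.fixture(scope="session")
def star_integer():
    """The normal-form grammar with published integer weights."""
    return load_builtin("Gsto_hat_star_integer")


@pytest.fixture(scope="session")
def language():
    """Exhaustively enumerated language, indexed by size, up to n = 12."""
    return {n: enumerate_language(n) for n in range(1, 13)}


@pytest.fixture(scope="session")
def weighted_table(star_integer):
    """Size tables of the published integer-weighted specification."""
    spec = grammar_to_spec(star_integer)
    return build_tables(spec, 14, fingerprint=star_integer.fingerprint())


@pytest.fixture(scope="session")
def uniform_table(star_integer):
    """Size tables with every weight set to 1 (uniform counting)."""
    uni = star_integer.with_weights({r.id: 1 for r in star_integer.rules},
                                    name="uniform")
    return build_tables(grammar_to_spec(uni), 14)


@pytest.fixture(scope="session")
def default_sampler():
    """Full pipeline for the bundled model, tables ready for small sizes."""
    s = StructureSampler.default(seed=20240901)
    s.ensure(60)
    return s
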
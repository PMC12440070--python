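"""Shared fixtures: score tables and the seeded composite-sequence suite."""
import pytest

import lodust as ld


@pytest.fixture(scope="session")
def model_uniform():
    return ld.gc_to_frequency_model(0.5, 7)


@pytest.fixture(scope="session")
def tables_small(model_uniform):
    """Reduced window (w=256) used by the oracle-comparison suite."""
    return ld.ScoreTables.build(model_uniform, w=256, T=0.6)


@pytest.fixture(scope="session")
def tables_mid(model_uniform):
    """w=1000 tables: roomy enough for kilobase fixtures, fast to scan."""
    return ld.ScoreTables.build(model_uniform, w=1000, T=0.6)


@pytest.fixture(scope="session")
def tables_default(model_uniform):
    """Published defaults: k=7, w=5000, T=0.6."""
    return ld.ScoreTables.build(model_uniform, w=5000, T=0.6)


def make_fixture(seed: int) -> str:
    """Deterministic composite sequence <= 2000 bp for the oracle suite.

    Cycles through homopolymer, short tandem repeat, 30-170 bp-unit tandem
    array (half of them 2% diverged), double-insert and pure-random hosts.
    """
    host = ld.random_dna(1500, 0.5, seed=1000 + seed)
    kind = seed % 5
    if kind == 0:
        ins = "A" * (60 + (seed % 3) * 40)
    elif kind == 1:
        u = 2 + seed % 4
        ins = ld.tandem_array(ld.RepeatSpec(u, 120 // u, 0.0, seed=2000 + seed))
    elif kind == 2:
        unit = 30 + (seed * 7) % 141
        div = 0.02 if seed % 2 else 0.0
        ins = ld.tandem_array(ld.RepeatSpec(unit, 6.0, div, seed=3000 + seed))
    elif kind == 3:
        ins = ld.tandem_array(ld.RepeatSpec(50, 5.0, 0.0, seed=4000 + seed))
        host = ld.implant(host, "A" * 70, 1100)
    else:
        return host
    pos = 200 + (seed * 131) % 600
    return ld.implant(host, ins, pos)


@pytest.fixture(scope="session")
def fixture_suite():
    """50 seeded composite sequences used by the agreement/validity checks."""
    return [(f"fx{seed}", make_fixture(seed)) for seed in range(50)]
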
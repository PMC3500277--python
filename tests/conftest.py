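import numpy as np
import pytest

from ssescore import energy_terms, statistics_builder
from ssescore import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def fixture_db():
    return sf.make_fixture_database(50, seed=17)


@pytest.fixture(scope="session")
def tables():
    return statistics_builder.default_tables()


@pytest.fixture(scope="session")
def clash_params():
    return energy_terms.default_clash_params()


@pytest.fixture(scope="session")
def toy_sheet():
    """Deterministic 3-strand antiparallel sheet."""
    rng = np.random.default_rng(0)
    return sf.make_toy_protein(sf.antiparallel_sheet(rng, 3), seed=3)


@pytest.fixture(scope="session")
def toy_bundle():
    """Deterministic 2-helix bundle."""
    rng = np.random.default_rng(1)
    return sf.make_toy_protein(sf.two_helix_bundle(rng), seed=4)


def format_pdb(records):
    """Minimal PDB text from (name, resname, chain, seq, xyz) atom tuples."""
    lines = []
    for i, (name, resname, chain, seq, xyz) in enumerate(records, start=1):
        field = name if len(name) == 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {field} {resname:>3s} {chain}{seq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
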
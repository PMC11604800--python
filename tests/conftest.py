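import pytest

from varsieve.fixtures import (FR_EXAMPLE, FixtureSpec, generate_fd,
                               generate_table, write_fixture_bundle)
from varsieve.schema import parse_fd

BUNDLE_SPEC = FixtureSpec(n_rows=300, seed=11)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A 300-row synthetic fixture bundle plus its ground-truth ledger."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(BUNDLE_SPEC, outdir)
    _, ledger = generate_table(BUNDLE_SPEC)
    return paths, ledger, BUNDLE_SPEC


@pytest.fixture(scope="session")
def bundle_schema():
    return parse_fd(generate_fd(BUNDLE_SPEC.n_samples))


@pytest.fixture
def annovar_schema():
    """The four-field schema of the worked FD example."""
    return parse_fd(
        "Name\tType\tdelimiter(req)\n"
        "Chr\tS\t\n"
        "Start\tI\t\n"
        "ExAC_ALL\tD\t\n"
        "Func.refGene\tS\t;\n"
    )


@pytest.fixture
def fr_example_text():
    return FR_EXAMPLE
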
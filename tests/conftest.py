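import pytest

from stitchkit import DesignParameters, generate_fixture


@pytest.fixture(scope="session")
def fixture_record():
    """1 kb deterministic pseudorandom input at 50% GC."""
    return generate_fixture(seed=1, length=1000, gc_fraction=0.5)


@pytest.fixture()
def default_params():
    return DesignParameters()


@pytest.fixture()
def fixture_fasta(tmp_path, fixture_record):
    path = tmp_path / "fixture.fa"
    path.write_text(f">{fixture_record.id}\n{fixture_record.seq}\n")
    return path
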
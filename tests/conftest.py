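import pytest

from fluxmodes import (
    FixtureParams,
    generate_fixture,
    toy_model,
    write_bundle,
    write_sbml,
)


@pytest.fixture(scope="session")
def bundle():
    return generate_fixture(FixtureParams(), seed=7)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, str(outdir))
    return paths


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture(scope="session")
def toy_sbml(toy, tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toynet.xml"
    write_sbml(toy, str(path))
    return str(path)
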
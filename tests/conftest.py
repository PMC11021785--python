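import pytest

from dilinet import deduplicate, load_dictionary, make_fixture_bundle, read_reports, read_synonyms


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The standard synthetic fixture bundle (seed 1), written once."""
    out = tmp_path_factory.mktemp("bundle")
    return make_fixture_bundle(out, seed=1)


@pytest.fixture(scope="session")
def synonyms(bundle):
    return read_synonyms(bundle["synonyms"])


@pytest.fixture(scope="session")
def meddra_dict(bundle):
    return load_dictionary(bundle["dict_dir"])


@pytest.fixture(scope="session")
def clean(bundle, synonyms):
    return deduplicate(read_reports(bundle["reports"]), synonyms)
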
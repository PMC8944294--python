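import pytest

from sbolbatch import fixtures, tableio
from sbolbatch.hub import RetryPolicy, login
from sbolbatch.mockhub import MockSynBioHub


@pytest.fixture()
def template_doc():
    return fixtures.make_template(seed=1)


@pytest.fixture()
def small_table(tmp_path):
    path = fixtures.make_library_table(3, seed=1, path=tmp_path / "lib_def.xlsx")
    return tableio.read_table(path)


@pytest.fixture()
def mock_hub():
    with MockSynBioHub() as hub:
        yield hub


@pytest.fixture()
def hub_session(mock_hub):
    return login(
        mock_hub.base_url,
        "demo",
        "secret",
        collection_url=mock_hub.collection_url,
        retry_policy=RetryPolicy(max_attempts=3, backoff=(0.01, 0.02)),
    )
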
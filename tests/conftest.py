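import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tmp_file(tmp_path):
    """Write text content to a temp file and return its path."""

    def write(content, name="fixture.txt"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return write
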
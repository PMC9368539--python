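import pytest

from crayrisk import ExposureScenario


@pytest.fixture
def default_scenario() -> ExposureScenario:
    """Study-default scenario (lognormal edible-tissue specs, 1000 LHS iterations)."""
    return ExposureScenario(seed=20260924)


@pytest.fixture
def concentration_csv(tmp_path):
    """Factory writing a concentration CSV and returning its path."""

    def _write(rows: list[str], header: str = "sample_id,source,region,tissue,concentration_ug_kg"):
        path = tmp_path / "records.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
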
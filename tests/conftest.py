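import pytest

from snprecover import SimulationConfig, simulate_panel
from snprecover.snp_metrics_io import SnpMetricsRecord, VariantKey


@pytest.fixture(scope="session")
def small_panel():
    """A modest multi-ancestry panel shared by read-only tests."""
    cfg = SimulationConfig(n_snps=20, n_strata=3, samples_per_stratum=20, seed=42)
    return simulate_panel(cfg)


@pytest.fixture
def make_record():
    """Factory for a valid record with overridable fields."""

    def _make(**kw):
        defaults = dict(
            sample_id="S1",
            snp_id="chr12:40340400:G:A",
            variant=VariantKey("chr12", 40340400, "G", "A"),
            r=1.0,
            theta=0.5,
            gentrain=0.8,
            genotype="AB",
            a_is_ref=True,
        )
        defaults.update(kw)
        return SnpMetricsRecord(**defaults)

    return _make
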
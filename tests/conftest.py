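import pytest

from plasmabm import (BiomarkerStudy, PipelineConfig, SimulationConfig,
                      generate_cohort)
from plasmabm.types import VariantCall


def make_variant(**kwargs) -> VariantCall:
    """A valid somatic SNV with overridable fields."""
    defaults = dict(
        patient_id="P0001", sample_id="P0001-C0", timepoint="C0", gene="TP53",
        chrom="17", pos=7_577_121, ref="C", alt="T", variant_type="SNV",
        consequence="nonsynonymous", vaf=0.05,
    )
    defaults.update(kwargs)
    return VariantCall(**defaults)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-patient synthetic cohort with the default study conditions."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_results(small_cohort):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BiomarkerStudy.from_cohort(small_cohort).fit()
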
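import pytest

from circalum.synth import GenotypeSpec, ProtocolSchedule


@pytest.fixture
def protocol() -> ProtocolSchedule:
    return ProtocolSchedule()


@pytest.fixture
def clean_genotype() -> GenotypeSpec:
    """Noiseless, undamped, transient-free rhythmic genotype."""
    return GenotypeSpec(
        noise_sd=0.0,
        damping_rate=0.0,
        transient_hours=0.0,
        fraction_rhythmic=1.0,
        period_freerun=24.0,
    )
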
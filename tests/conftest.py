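import pytest

from motifcons import (
    CdsSpec,
    PanelSpec,
    simulate_cds_alignment,
    simulate_promoter_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """The study-condition panel: 21 with-site / 28 without-site species."""
    return simulate_promoter_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def default_cds():
    """A neutral-control codon alignment with known fourfold columns."""
    return simulate_cds_alignment(CdsSpec(seed=12))
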
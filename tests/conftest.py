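import pytest

from csnptrack import (
    load_panel_loci,
    load_panel_params,
    load_panel_frequencies,
    load_trio_evidence,
)
from csnptrack.wes_extract import call_genotype


@pytest.fixture(scope="session")
def panel_params():
    return load_panel_params()


@pytest.fixture(scope="session")
def panel_freqs():
    return {f.rsid: f for f in load_panel_frequencies()}


@pytest.fixture(scope="session")
def trio_evidence():
    return load_trio_evidence()


@pytest.fixture(scope="session")
def panel_loci():
    return load_panel_loci()


@pytest.fixture(scope="session")
def trio_profiles(trio_evidence):
    """Called genotypes (default thresholds) of the packaged WES trio."""
    return {
        sample: {rsid: call_genotype(ev)[0] for rsid, ev in loci.items()}
        for sample, loci in trio_evidence.items()
    }
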
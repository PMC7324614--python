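import numpy as np
import pytest

import sumiseq as sq
from sumiseq.simulate import synthetic_umi_layout


@pytest.fixture(scope="session")
def germline():
    return sq.synthetic_germline(n_v=4, n_j=3, seed=0)


def spec_for(config, germline):
    off, length = synthetic_umi_layout(config)
    return sq.build_primer_spec(
        germline,
        umi_length=config.umi_length,
        synthetic_umi_offset=off,
        synthetic_umi_length=length,
    )


@pytest.fixture(scope="session")
def clean_sim(germline):
    """Error-free simulated sample: everything is exactly recoverable."""
    config = sq.SimulationConfig(
        n_templates=20,
        sequencing_depth=600,
        seq_error_rate=0.0,
        quality_pass_fraction=1.0,
        seed=7,
    )
    templates, amplicons, reads, truth = sq.simulate_sumi(config, germline)
    return {
        "config": config,
        "templates": templates,
        "amplicons": amplicons,
        "reads": reads,
        "truth": truth,
        "spec": spec_for(config, germline),
    }


@pytest.fixture(scope="session")
def noisy_sim(germline):
    """Simulated sample with sequencing error and quality failures."""
    config = sq.SimulationConfig(
        n_templates=40,
        sequencing_depth=4000,
        seq_error_rate=0.005,
        seed=11,
    )
    templates, amplicons, reads, truth = sq.simulate_sumi(config, germline)
    return {
        "config": config,
        "templates": templates,
        "amplicons": amplicons,
        "reads": reads,
        "truth": truth,
        "spec": spec_for(config, germline),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
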
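import numpy as np
import pytest

from d2okinetics.simulate import (
    NoiseModel,
    NucleicTruth,
    ProteinTruth,
    StudyConfig,
    generate_study,
)

TRUE_K = {"25wk": 0.0139, "90wk": 0.0090}
TRUE_CONC = {"25wk": 500.0, "90wk": 450.0}


def small_config(noise_cv: float = 0.0, ratio_sd: float = 0.0,
                 serum_cv: float = 0.0) -> StudyConfig:
    """Compact two-age study: one turning-over protein, one inert collagen."""
    return StudyConfig(
        age_groups={"25wk": 4, "90wk": 3},
        proteins=[
            ProteinTruth("DCN", ["ASYSAVSLYGNPVR", "LGLGHNQIR", "VVQCSDLGLDK"],
                         dict(TRUE_CONC), dict(TRUE_K)),
            ProteinTruth("COL2A1", ["GPPGPQGAR"],
                         {"25wk": 300.0, "90wk": 200.0},
                         {"25wk": 0.0, "90wk": 0.0}),
        ],
        nucleic=[NucleicTruth("DNA", {"25wk": 0.6, "90wk": 0.6}),
                 NucleicTruth("RNA", {"25wk": 0.6, "90wk": 0.6})],
        noise=NoiseModel(area_cv=noise_cv, ratio_sd=ratio_sd,
                         serum_cv=serum_cv),
    )


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free synthetic study shared across tests (read-only)."""
    return generate_study(small_config(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
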
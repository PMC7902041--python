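import numpy as np
import pandas as pd
import pytest

from ocuqtl import simkit


@pytest.fixture(scope="session")
def small_map() -> simkit.MarkerMap:
    """Compact 3-chromosome map for fast genetics tests."""
    rows = []
    for chrom in ("1", "2", "3"):
        for i, cm in enumerate(np.arange(0.0, 61.0, 4.0)):
            rows.append(
                {"name": f"c{chrom}m{i:02d}", "chromosome": chrom,
                 "cM": float(cm), "Mb": float(2.0 * cm)}
            )
    return simkit.MarkerMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def noise_free_protocol() -> simkit.Protocol:
    return simkit.Protocol(pressure_noise_sd=0.0, flow_noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_trace(noise_free_protocol):
    """One noise-free, creep-off eye under the default stepped protocol."""
    eye = simkit.GroundTruthEye(
        eye_id="eye1", strain="S1", mass=22.06,
        phi_r_true=45.0, gamma_true=10.0, facility_true=0.07,
    )
    return simkit.simulate_perfusion_trace(eye, noise_free_protocol, seed=101)
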
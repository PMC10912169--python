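import numpy as np
import pytest

from afmspeech.signal_model import AFMComponentParams, ToneParams


@pytest.fixture(scope="session")
def low_component() -> AFMComponentParams:
    """Well-behaved low-band component used across modules."""
    return AFMComponentParams(
        amplitude=1.0,
        carrier=0.15 * np.pi,
        am_tones=(ToneParams(0.25, 0.035, 0.5), ToneParams(0.12, 0.08, -1.0)),
        fm_tones=(ToneParams(0.20, 0.030, 0.8), ToneParams(0.10, 0.065, -0.6)),
    )


@pytest.fixture(scope="session")
def high_component() -> AFMComponentParams:
    return AFMComponentParams(
        amplitude=0.8,
        carrier=0.55 * np.pi,
        am_tones=(ToneParams(0.20, 0.040, -0.3), ToneParams(0.10, 0.085, 1.2)),
        fm_tones=(ToneParams(0.15, 0.033, -1.5), ToneParams(0.08, 0.070, 0.9)),
    )


def flat_truth(c1: AFMComponentParams, c2: AFMComponentParams) -> dict[str, float]:
    """Generating parameters keyed by the 28-feature schema names."""
    out = {}
    for prefix, comp in (("c1", c1), ("c2", c2)):
        for k, v in comp.to_dict().items():
            out[f"{prefix}_{k}"] = v
    return out


def component_oracle(params: AFMComponentParams, n: np.ndarray) -> np.ndarray:
    """Independent direct evaluation of the two-tone AM/FM formula."""
    d = params.to_dict()
    am = (
        1.0
        + d["mu_a1"] * np.cos(d["omega_a1"] * n + d["theta_a1"])
        + d["mu_a2"] * np.cos(d["omega_a2"] * n + d["theta_a2"])
    )
    phase = (
        d["omega_c"] * n
        + d["mu_f1"] * np.sin(d["omega_f1"] * n + d["theta_f1"])
        + d["mu_f2"] * np.sin(d["omega_f2"] * n + d["theta_f2"])
    )
    return d["A"] * am * np.cos(phase)
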
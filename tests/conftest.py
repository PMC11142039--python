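import numpy as np
import pytest

from headbem import (
    HeadModel,
    build_phantom_3,
    conductivity_preset,
    fibonacci_layout,
    icosphere,
    project_to_skin,
)

RADII_4SHELL = (0.092, 0.086, 0.080, 0.078)


def four_shell_phantom(n_subdiv: int, radii=RADII_4SHELL) -> HeadModel:
    """Skin/skull/CSF/GM nested icospheres with IT'IS conductivities and
    the thin (2 mm) CSF–GM gap."""
    cond = conductivity_preset("ITIS7")
    tissues = ("skin", "skull", "csf", "gm")
    sig = [cond[t] for t in tissues]
    return HeadModel(
        interfaces=tuple(icosphere(r, n_subdiv) for r in radii),
        names=tissues,
        sigma_in=tuple(sig),
        sigma_out=(0.0, sig[0], sig[1], sig[2]),
        refinable=(False, True, True, True),
    )


def fixed_eval_points(n: int = 256, radius: float = 0.092) -> np.ndarray:
    """Resolution-independent evaluation points on the skin sphere."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    phi = i * np.pi * (1.0 + np.sqrt(5.0))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@pytest.fixture(scope="session")
def m3_small() -> HeadModel:
    """3-layer phantom at low resolution (320 facets per shell)."""
    return build_phantom_3(n_subdiv=2)


@pytest.fixture(scope="session")
def el64(m3_small):
    return project_to_skin(fibonacci_layout(64, 0.65), m3_small.interfaces[0])


@pytest.fixture(scope="session")
def engine_small(m3_small, el64):
    from headbem import LeadFieldEngine

    return LeadFieldEngine(m3_small, el64)
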
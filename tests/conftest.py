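import pytest

from switchnoise import cli_io
from switchnoise.model_core import Architecture


def scaled_default_params(arch: Architecture, A_T: int, alpha: float | None = None):
    """Shipped defaults rescaled to a smaller activator pool.

    Dissociation constants scale with A_T so the normalized constants (and
    hence the dose-response shape) are preserved.
    """
    p = cli_io.default_params(arch)
    if not arch.sequestration_family:
        return p
    s = A_T / p.A_T
    return p.replace(
        A_T=A_T,
        alpha=p.alpha if alpha is None else alpha,
        K_a=p.K_a * s,
        K_s=p.K_s * s,
        K_b=None if p.K_b is None else p.K_b * s,
        K_d=None if p.K_d is None else p.K_d * s,
    )


@pytest.fixture(scope="session")
def default_params():
    return cli_io.default_params
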
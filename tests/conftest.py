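import numpy as np
import pytest

from msoenergy import CellSpec, discretize_cell


@pytest.fixture(scope="session")
def default_spec():
    return CellSpec()


@pytest.fixture(scope="session")
def default_grid(default_spec):
    return discretize_cell(default_spec)


def analytic_input_resistance(spec, g_density_mS_cm2=None):
    """Independent oracle: soma + two sealed finite cables.

    G = g A_soma + 2 G_inf tanh(L / lambda) with G_inf = 1 / (r_a lambda),
    evaluated in closed form (no compartmental simulation).  Returns MOhm.
    """
    g = (spec.g_L if g_density_mS_cm2 is None else g_density_mS_cm2) * 1e-3
    a_soma = spec.soma_area * 1e-8
    if spec.dendrite_length <= 0:
        return 1.0 / (g * a_soma) / 1e6
    d = spec.dendrite_diameter * 1e-4
    length = spec.dendrite_length * 1e-4
    lam = np.sqrt(d / (4.0 * spec.R_a * g))
    r_a = 4.0 * spec.R_a / (np.pi * d ** 2)
    g_inf = 1.0 / (r_a * lam)
    g_tot = g * a_soma + 2.0 * g_inf * np.tanh(length / lam)
    return 1.0 / g_tot / 1e6
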
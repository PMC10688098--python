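import numpy as np
import pytest

from pkashift import CompoundParams, GeneratorConfig, standard_setup


@pytest.fixture
def reference_acid() -> CompoundParams:
    """Reference acid: pKa 7.0, intrinsic solubility 100 uM."""
    return CompoundParams(7.0, 100e-6, "acid")


@pytest.fixture
def sparingly_soluble_acid() -> CompoundParams:
    """Phenolic acid with pKa 6.85 and S = 75 uM."""
    return CompoundParams(6.85, 75e-6, "acid")


@pytest.fixture
def amine_base() -> CompoundParams:
    """Amine base: pKa 9.60, S = 0.27 mM; shift runs acidic."""
    return CompoundParams(9.60, 0.27e-3, "base")


@pytest.fixture
def ideal_acid() -> CompoundParams:
    """No-aggregation acid (A = 0)."""
    return CompoundParams(7.0)


def ph_grid_oracle(params, c_na, c_cl, c_total, step=1e-5):
    """Independent pH solver: dense grid scan minimizing |charge residual|.

    Recomputes the residual from the raw equilibrium relations (mass
    balance, mass action, water product, electroneutrality) without calling
    the package's solver.
    """
    ph = np.arange(step, 14.0, step)
    h = 10.0 ** (-ph)
    oh = 10.0 ** (ph - params.pkw)
    ka = 10.0 ** (-params.pka_intrinsic)
    a = 0.0 if np.isinf(params.s_intrinsic) else 1.0 / params.s_intrinsic
    if params.polarity.value == "acid":
        ratio = ka / h
        charged_sign = -1.0
    else:
        ratio = h / ka
        charged_sign = +1.0
    charged = ratio * c_total / (1.0 + ratio + a * c_total)
    residual = c_na + h - c_cl - oh + charged_sign * charged
    return float(ph[np.argmin(np.abs(residual))])
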
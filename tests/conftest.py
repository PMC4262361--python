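import numpy as np
import pytest

from seepcomm.core_data_io import CloneLibrary, IncubationSeries, Ribotype
from seepcomm.endmember_mixing import default_ktl_model


@pytest.fixture
def ktl_model():
    """Seawater-like saline vs Taiwanese river-water end members."""
    return default_ktl_model()


@pytest.fixture
def bact80_library():
    """80 °C bacterial library: 36 clones over 3 fermenter ribotypes."""
    return CloneLibrary(
        domain="bacteria", treatment="80C", n_clones=36,
        ribotypes=(
            Ribotype("Thermotoga_R1", 19, "Thermotoga"),
            Ribotype("Dictyoglomus_R1", 8, "Dictyoglomus"),
            Ribotype("Propionibacterium_R1", 9, "Propionibacterium"),
        ),
    )


@pytest.fixture
def arch80_library():
    """80 °C archaeal library: a single Archaeoglobus ribotype of 35 clones."""
    return CloneLibrary(
        domain="archaea", treatment="80C", n_clones=35,
        ribotypes=(Ribotype("Archaeoglobus_R1", 35, "Archaeoglobus"),),
    )


def make_logistic_series(S0=2000.0, S_inf=0.0, k=0.028, t0=360.0,
                         t=None, temperature=80.0, noise_sd=0.0, rng=None):
    """Falling-logistic depletion series, optionally with Gaussian noise."""
    if t is None:
        t = np.linspace(0.0, 720.0, 15)
    t = np.asarray(t, dtype=float)
    s = S_inf + (S0 - S_inf) / (1.0 + np.exp(k * (t - t0)))
    if noise_sd > 0:
        s = s + (rng or np.random.default_rng(0)).normal(0.0, noise_sd, t.shape)
    return IncubationSeries(temperature_C=temperature, times_h=t,
                            sulfate_uM=np.clip(s, 0.0, None))
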
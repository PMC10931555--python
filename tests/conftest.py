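import numpy as np
import pytest

from bilayerlab.synthetic import (EndothermParams, FluorescenceParams,
                                  LamellarModelParams, SansModelParams)


@pytest.fixture
def clean_sans_params():
    """Noise-free, unsmeared Guinier-sheet curve with no background."""
    def make(thickness=3.88, **kw):
        defaults = dict(model_kind="guinier_sheet", thickness_true=thickness,
                        scale_C=1.0, background_B=0.0, wavelength_spread=0.0,
                        noise_level=0.0, seed=0)
        defaults.update(kw)
        return SansModelParams(**defaults)
    return make


@pytest.fixture
def clean_lamellar_params():
    def make(d=7.8, **kw):
        defaults = dict(d_true=d, n_orders=2, noise_level=0.0, seed=0)
        defaults.update(kw)
        return LamellarModelParams(**defaults)
    return make


@pytest.fixture
def clean_endotherm_params():
    def make(**kw):
        defaults = dict(Tm_true=28.1, dH_true=18.0, fwhm_true=12.5,
                        noise_level=0.0, seed=0)
        defaults.update(kw)
        return EndothermParams(**defaults)
    return make


@pytest.fixture
def clean_fluor_params():
    def make(eta=1.13, **kw):
        defaults = dict(eta_true=eta, noise_level=0.0, seed=0)
        defaults.update(kw)
        return FluorescenceParams(**defaults)
    return make


@pytest.fixture
def wide_T_grid():
    """Temperature grid spanning the default peak by well over 2 FWHM."""
    return np.arange(-10.0, 66.0, 0.05)
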
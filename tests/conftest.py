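import numpy as np
import pytest

from stimcal import opsins, photometry, spectra


@pytest.fixture(scope="session")
def grid():
    return opsins.default_grid()


@pytest.fixture(scope="session")
def mouse_curves(grid):
    preset = opsins.species_preset("mouse")
    return {o.name: o.sensitivity(grid) for o in preset.cone_opsins}


@pytest.fixture(scope="session")
def mouse_leds(grid):
    """Modelled band-pass LED/filter pairs for a dichromatic mouse stimulator."""
    green = spectra.synth_led_spectrum(
        spectra.LedModel("green", peak=576.0, fwhm=10.0, passband=(571.0, 581.0),
                         peak_power=100.0), grid)
    uv = spectra.synth_led_spectrum(
        spectra.LedModel("UV", peak=387.0, fwhm=11.0, passband=(381.5, 392.5),
                         peak_power=100.0), grid)
    return {"green": green, "UV": uv}


@pytest.fixture(scope="session")
def mouse_matrix(mouse_leds, mouse_curves):
    geom = photometry.StimulusGeometry.from_spot_diameter(1000.0)
    return photometry.build_activation_matrix(
        [mouse_leds["green"], mouse_leds["UV"]],
        [mouse_curves["S"], mouse_curves["M"]],
        geom,
    )


@pytest.fixture(scope="session")
def printed_mouse_matrix():
    """Activation matrix holding the measured max-brightness rates (P*/s):
    green drives only M (19.5e3), UV drives S strongly (19.2e3) and M
    weakly through the beta band (3.8e3)."""
    r = np.array([[0.0, 19.5e3], [19.2e3, 3.8e3]])
    return photometry.ActivationMatrix(
        ("green", "UV"), ("S", "M"), r, np.zeros_like(r))
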
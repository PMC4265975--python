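import numpy as np
import pytest

from sonasim import apps
from sonasim.acoustics import MediumProperties, layout_elements


@pytest.fixture(scope="session")
def water():
    # lossless water for field-verification tests
    return MediumProperties(sound_speed_m_s=1500.0, density_kg_m3=1000.0,
                            attenuation_np_m_mhz=0.0, absorption_fraction=1.0)


@pytest.fixture(scope="session")
def array_256():
    return layout_elements()


@pytest.fixture(scope="session")
def hifu_pattern_result():
    """The full 'HIFU' pattern run at default desk-scale settings.

    Session-scoped: the run takes a couple of minutes and several tests
    interrogate different aspects of the same result.
    """
    return apps.run_hifu_pattern()


@pytest.fixture(scope="session")
def element_scan_result():
    """Full 256-element scan at the default per-channel budget."""
    return apps.run_element_scan()


def gaussian_hotspot(grid, peak_c, sigma_mm, baseline_c=20.0):
    xx, yy, zz = np.meshgrid(*grid.axes_mm(), indexing="ij")
    return baseline_c + peak_c * np.exp(
        -(xx ** 2 + yy ** 2 + zz ** 2) / (2.0 * sigma_mm ** 2)
    )
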
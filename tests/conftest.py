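import numpy as np
import pytest

import episense as ep

#: Half-resolution experiment panel used throughout the tests.
PITCH = ep.DEFAULT_PITCH_MM * 2
PANEL = (384, 512)


def render(beam, scene=None, noise=None, pitch=PITCH, panel=PANEL):
    return ep.render_image(beam, scene, noise, pitch_mm=pitch, panel_shape=panel)


@pytest.fixture(scope="session")
def open_field_10():
    """Nominal 10 cm x 10 cm open field image at half resolution."""
    return render(ep.open_field(10.0, 10.0))


@pytest.fixture(scope="session")
def jaw_shift_pair(open_field_10):
    """(baseline, errant) pair: X2 jaw opened 1 mm at isocenter, i.e. the
    field edge translated 1.5 mm at the detector plane."""
    beam, _ = ep.inject_error(ep.open_field(10.0, 10.0), None, "jaw_shift", jaw="X2", shift_mm=1.0)
    return open_field_10, render(beam)


@pytest.fixture(scope="session")
def mlc_shift_pair():
    """(baseline, errant) pair for the MLC-shaped field with every 4th open
    leaf of the left bank moved 1 mm at isocenter."""
    nominal = ep.mlc_shaped_field()
    baseline = render(nominal)
    errant_beam, _ = ep.inject_error(
        nominal, None, "mlc_shift", leaves=[25, 29, 33], bank="left", shift_mm=1.0
    )
    return baseline, render(errant_beam)


@pytest.fixture
def uniform_pair():
    """Flat 64 x 64 baseline of 100 dose units and a +0.5% scaled copy."""
    ref = ep.DoseImage(np.full((64, 64), 100.0), PITCH, 1500.0)
    ev = ep.DoseImage(ref.values * 1.005, PITCH, 1500.0, ref.origin)
    return ref, ev
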
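"""Shared constructors for synthetic pupil maps used by the test suite."""

import numpy as np

from ocusim.metrics import OpdMap


def disk_map(n: int, na: float = 0.1, defocus_waves: float = 0.0,
             wavelength: float = 587.562) -> OpdMap:
    """Circular-pupil OPD map with optional quadratic (defocus) phase."""
    c = (np.arange(n) + 0.5) / n * 2 - 1
    xx, yy = np.meshgrid(c, c)
    mask = xx**2 + yy**2 <= 1.0
    opd = defocus_waves * (xx**2 + yy**2)
    opd = np.where(mask, opd - opd[mask].mean(), 0.0)
    return OpdMap(opd=opd, mask=mask, wavelength=wavelength, na=na,
                  ref_sphere_radius=20.0, chief_point=np.zeros(2))
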
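"""Circular geometry on the 180-degree feature space.

All response domains (orientation, color, luminance) are represented on a
common circle spanning 180 units, so the maximal distance between two
values is 90.  For von Mises sampling and density evaluation, angles are
doubled onto the full 360-degree circle and halved back — the standard
convention for orientation-like spaces.
"""

from __future__ import annotations

import numpy as np

SPAN = 180.0  # period of the feature space, degrees
MAX_DIST = SPAN / 2.0  # maximal circular distance, degrees


def wrap(x):
    """Wrap angles into [0, 180)."""
    return np.mod(x, SPAN)


def signed_error(response, target):
    """Signed circular difference response − target, in [−90, 90)."""
    return np.mod(np.asarray(response, dtype=float) - target + MAX_DIST, SPAN) - MAX_DIST


def circ_dist(a, b):
    """Minimal circular distance on the 180-degree space, in [0, 90]."""
    return np.abs(signed_error(a, b))


def doubled_radians(err_deg):
    """Map a signed error on the 180-space to radians on the doubled circle."""
    return np.deg2rad(2.0 * np.asarray(err_deg, dtype=float))
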
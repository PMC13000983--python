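"""Angle bookkeeping in 180-degree-periodic orientation space.

Orientations live on [0, 180); all tuning computations double the angle to map
the space onto the full circle.
"""

from __future__ import annotations

import numpy as np


def fold_offset(delta_deg):
    """Fold a signed angular difference into (-90, +90] degrees.

    Orientation space is 180-degree periodic, so +100 degrees is the same
    offset as -80 degrees.
    """
    scalar = np.isscalar(delta_deg)
    d = np.mod(np.asarray(delta_deg, dtype=float), 180.0)
    out = np.where(d > 90.0, d - 180.0, d)
    return float(out) if scalar else out


def circ_dist_180(a_deg, b_deg):
    """Unsigned circular distance between two orientations, in [0, 90]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)
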
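"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def wrap_phase(phi):
    """Wrap angles into the half-open interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)
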
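"""Continuously differentiable transition functions.

Half-cosine ramps replace hard cutoffs so that every geometric feature (and
thus every potential evaluated on it) varies smoothly with the coordinates.
"""
from __future__ import annotations

import numpy as np

__all__ = ["step_down", "step_up", "half_cosine_ramp"]


def step_down(x, lo: float, hi: float):
    """Half-cosine step from 1 (at ``x <= lo``) down to 0 (at ``x >= hi``)."""
    x = np.asarray(x, dtype=float)
    t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    out = 0.5 * (1.0 + np.cos(np.pi * t))
    return out if out.ndim else float(out)


def step_up(x, lo: float, hi: float):
    """Half-cosine step from 0 (at ``x <= lo``) up to 1 (at ``x >= hi``)."""
    x = np.asarray(x, dtype=float)
    res = 1.0 - step_down(x, lo, hi)
    return res if np.ndim(x) else float(res)


def half_cosine_ramp(angle_deg):
    """Ramp h with h(0 deg) = 0 and h(90 deg) = 1 via half of a cosine.

    ``h(a) = (1 - cos(pi * a / 90)) / 2`` for ``a`` in [0, 90]; values outside
    the range are clamped.
    """
    a = np.clip(np.asarray(angle_deg, dtype=float), 0.0, 90.0)
    out = 0.5 * (1.0 - np.cos(np.pi * a / 90.0))
    return out if out.ndim else float(out)
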
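"""Shared rendering helpers and independent oracles for the test suite."""

import numpy as np


def render_disk(shape=(101, 101), center=(50.0, 50.0), radius=20.0,
                value=1.0, background=0.0):
    """Binary-by-center-test rasterized disk (x, y convention for center)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    inside = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    return np.where(inside, value, background).astype(float), inside


def render_ellipse(shape=(101, 101), center=(50.0, 50.0), semi_axes=(20.0, 10.0),
                   value=1.0, background=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    a, b = semi_axes
    inside = ((xx - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2 <= 1.0
    return np.where(inside, value, background).astype(float), inside


def naive_lncc(I, J, window):
    """Literal per-window double-loop of the modified LNCC: the oracle.

    For every fully interior window, compute the NCC over that window and
    take its absolute value; zero-variance windows contribute 0.
    """
    I = np.asarray(I, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    h, w = I.shape
    out = np.zeros((h - window + 1, w - window + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            wi = I[r:r + window, c:c + window]
            wj = J[r:r + window, c:c + window]
            di = wi - wi.mean()
            dj = wj - wj.mean()
            den = np.sqrt((di**2).sum() * (dj**2).sum())
            if den <= 1e-12 * window * window * max(np.abs(I).max(), np.abs(J).max(), 1.0) ** 2:
                out[r, c] = 0.0
            else:
                out[r, c] = abs((di * dj).sum() / den)
    return out
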
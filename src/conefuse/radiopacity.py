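"""Contrast-agent mixing calculator for planning marker radiopacity.

3D-printed markers are made visible in CT by blending an iodine-based
contrast agent into the printing resin.  With the attenuation of the pure
resin and the pure contrast agent known (in Hounsfield units), the volume
fraction ``k`` of contrast agent needed to hit a target CT number follows
from linear mixing:

    k = (CT_goal - CT_resin) / (CT_CA - CT_resin)

The achievable range is bounded by the two pure-material values; targets
outside that interval produce a warning (the mix is then clamped physically,
not numerically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


class DegenerateMixtureError(ValueError):
    """Raised when resin and contrast agent have identical attenuation."""


def mixing_coefficient(ct_goal: float, ct_resin: float, ct_ca: float) -> float:
    """Mixing fraction of contrast agent required to reach ``ct_goal``.

    Parameters
    ----------
    ct_goal, ct_resin, ct_ca:
        Target, pure-resin and pure-contrast-agent CT numbers in HU.

    Returns
    -------
    float
        The dimensionless mixing fraction ``k``.  Values outside [0, 1]
        are returned as computed but trigger a ``UserWarning`` stating the
        achievable HU range, since the attainable attenuation is bounded
        by the two pure materials.
    """
    if ct_ca == ct_resin:
        raise DegenerateMixtureError(
            "resin and contrast agent attenuation are identical "
            f"({ct_resin} HU); mixing fraction is undefined"
        )
    k = (ct_goal - ct_resin) / (ct_ca - ct_resin)
    if not 0.0 <= k <= 1.0:
        lo, hi = sorted((ct_resin, ct_ca))
        warnings.warn(
            f"target {ct_goal} HU is outside the achievable range "
            f"[{lo}, {hi}] HU (k = {k:.4g}); the mixture cannot reach it",
            UserWarning,
            stacklevel=2,
        )
    return k


def predicted_ct(k: float, ct_resin: float, ct_ca: float) -> float:
    """CT number of a mixture with contrast-agent fraction ``k``.

    Exact algebraic inverse of :func:`mixing_coefficient`.
    """
    return ct_resin + k * (ct_ca - ct_resin)


@dataclass(frozen=True)
class RadiopacityMix:
    """A planned resin / contrast-agent mixture."""

    ct_resin: float
    ct_ca: float
    ct_goal: float

    @property
    def k(self) -> float:
        return mixing_coefficient(self.ct_goal, self.ct_resin, self.ct_ca)

    @property
    def achievable(self) -> bool:
        lo, hi = sorted((self.ct_resin, self.ct_ca))
        return lo <= self.ct_goal <= hi
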
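"""Translation/scale-invariant assignment of detected markers to a known layout."""

from __future__ import annotations

from itertools import permutations
from typing import Mapping, Sequence

import numpy as np

__all__ = ["AmbiguousMatchError", "match_positions"]


class AmbiguousMatchError(ValueError):
    """Raised when two assignments explain the layout (near-)equally well."""


def _normalize(pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    centered = pts - pts.mean(axis=0)
    rms = np.sqrt((centered**2).sum(axis=1).mean())
    return centered / max(rms, 1e-30)


def match_positions(
    points_xy: np.ndarray,
    layout: Mapping[str, Sequence[float]],
    ambiguity_margin: float = 1e-3,
) -> dict[str, int]:
    """Assign each layout entry the candidate point that best reproduces the layout.

    Both point sets are normalized (centroid removed, scaled to unit RMS),
    making the assignment invariant to global translation and isotropic
    scaling — but deliberately *not* to rotation, since the approximate
    marker layout fixes the section's orientation.  The minimum
    total-squared-distance assignment over all injective mappings is
    returned (exhaustive; marker counts are small).

    Raises
    ------
    AmbiguousMatchError
        If the best and second-best assignments differ by less than
        ``ambiguity_margin`` per marker (normalized units), e.g. for a
        symmetric layout.
    ValueError
        If there are fewer candidate points than layout entries.
    """
    keys = sorted(layout)
    m = len(keys)
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    n = len(pts)
    if n < m:
        raise ValueError(f"{n} candidate points for {m} layout entries")
    lay_n = _normalize(np.array([layout[k] for k in keys]))
    pts_n = _normalize(pts)

    # sections can land on the slide rotated by 180 degrees; evaluate both
    # orientations so a symmetric layout is flagged instead of silently
    # assigned the wrong way round
    costs: list[tuple[float, tuple[int, ...]]] = []
    for oriented in (pts_n, -pts_n):
        for perm in permutations(range(n), m):
            cost = float(((oriented[list(perm)] - lay_n) ** 2).sum())
            costs.append((cost, perm))
    costs.sort(key=lambda t: t[0])
    best_cost, best_perm = costs[0]
    for cost, perm in costs[1:]:
        if perm == best_perm:
            continue
        if cost - best_cost < ambiguity_margin * m:
            raise AmbiguousMatchError(
                f"assignment ambiguous: best cost {best_cost:.4g} vs runner-up "
                f"{cost:.4g}; the marker layout may be symmetric")
        break
    return {k: idx for k, idx in zip(keys, best_perm)}
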
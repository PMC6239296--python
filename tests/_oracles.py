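"""Independent numerical oracles used only by the tests."""

from __future__ import annotations

import math


def bisect_wm1(z: float, iters: int = 200) -> float:
    """Solve w * e**w = z for the branch w <= -1 by pure bisection.

    On (-inf, -1] the map w -> w e^w is strictly decreasing, so the root
    is bracketed by [-750, -1] for any z in (-1/e, 0).
    """
    assert -1.0 / math.e < z < 0.0
    lo, hi = -750.0, -1.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid * math.exp(mid) > z:
            lo = mid  # f(mid) > z: mid is left of the root
        else:
            hi = mid
        if hi - lo < 1e-14 * max(1.0, abs(hi)):
            break
    return 0.5 * (lo + hi)
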
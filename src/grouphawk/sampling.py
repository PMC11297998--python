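"""Random sampling of valid societies for property tests and sweeps.

The sampler draws parameter sets uniformly over comfortably interior
ranges: sharing weights away from exact degeneracies, division biases away
from the d_c in {0, 1} singularities, and cost/benefit ratios respecting
C > V.  It deliberately spans group sizes and class splits well beyond any
single worked example so that algebraic identities (payoff conservation,
threshold continuity, monotonicity) are exercised across the parameter
space rather than at one point.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .payoffs import ModelConfig, class_payoffs

__all__ = ["random_model_configs"]


def random_model_configs(
    rng: np.random.Generator,
    n: int,
    *,
    omega_min: float = 0.0,
    require_nondegenerate: bool = False,
    min_preference_gap: float = 1e-6,
    max_tries_factor: int = 50,
) -> List[ModelConfig]:
    """Draw ``n`` valid societies uniformly over interior parameter ranges.

    Parameters
    ----------
    rng
        Source of randomness (pass a seeded ``numpy.random.Generator``).
    omega_min
        Lower bound of the omega range (set > 0 to exclude unshared
        societies, where the follower component of the dynamics is
        selectively neutral).
    require_nondegenerate
        Reject draws whose clamped class preferences are closer than
        ``min_preference_gap`` (relative), i.e. societies on or near the
        equilibrium continuum.
    """
    out: List[ModelConfig] = []
    tries = 0
    limit = max_tries_factor * max(n, 1)
    while len(out) < n and tries < limit:
        tries += 1
        v_total = 1.0
        config = ModelConfig(
            omega=float(rng.uniform(omega_min, 1.0)),
            epsilon=float(rng.uniform(0.05, 0.95)),
            n_group=int(rng.integers(4, 201)),
            v_total=v_total,
            c_total=float(v_total * rng.uniform(1.2, 5.0)),
            d_v=float(rng.uniform(0.05, 0.95)),
            d_c=float(rng.uniform(0.05, 0.95)),
        )
        if require_nondegenerate:
            pay = class_payoffs(config)
            vt_l = min(pay.vtilde_leader, 1.0)
            vt_f = min(pay.vtilde_follower, 1.0)
            gap = abs(vt_l - vt_f) / max(vt_l, vt_f, 1.0)
            if gap < min_preference_gap:
                continue
        out.append(config)
    if len(out) < n:
        raise RuntimeError(
            f"could only sample {len(out)}/{n} configs within {limit} tries"
        )
    return out
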
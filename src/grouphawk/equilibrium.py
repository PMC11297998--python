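"""Closed-form equilibria of the collective Hawk-Dove game and the
three-regime classification.

With clamped class preferences vt_L = min(V_L/C_L, 1) and
vt_F = min(V_F/C_F, 1), the unique stable equilibrium is piecewise in the
sharing weight omega.  When leaders are advantaged (vt_L > vt_F):

* ``leader control`` (omega below a lower threshold): leaders keep the
  collective P at their own preference vt_L by inflating their strategy,
  P_L* = vt_L (eps + (1 - eps) omega) / eps, while followers sit at 0.
* ``compromise`` (omega between the thresholds): both classes are pinned
  at the extremes (P_L*, P_F*) = (1, 0) and the collective outcome
  P* = eps / (eps + omega (1 - eps)) slides from vt_L down to vt_F — the
  "loudest voice prevails" pattern, and the reason increased sharing
  pacifies leader-advantaged societies ("democratic peace").
* ``follower control`` (omega above the upper threshold): followers pin P
  at vt_F with P_F* = vt_F - (eps / ((1 - eps) omega)) (1 - vt_F) and
  leaders saturate at 1.

The follower-advantaged case mirrors this with the roles of 0 and 1
swapped and P* = omega (1 - eps) / (eps + omega (1 - eps)) rising through
the compromise window ("democratic war").  The compromise expression
equals the adjacent control value exactly at each threshold, so P*(omega)
is continuous.  When the two preferences coincide the class nullclines
merge and a continuum of equilibria shares the collective P = vt; only P*
is then determinate.

Boundary ties: an omega exactly at a threshold classifies as compromise
(the control conditions are strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

from .errors import DegenerateRegimeError
from .payoffs import ClassPayoffs, ModelConfig, class_payoffs

__all__ = [
    "Regime",
    "AnalyticEquilibrium",
    "regime_thresholds",
    "solve_equilibrium",
    "classify_regime",
    "DEGENERACY_RTOL",
]

#: Relative tolerance below which the two class preferences are treated as
#: equal (degenerate continuum) — exact float equality is brittle.
DEGENERACY_RTOL = 1e-12


class Regime(str, Enum):
    LEADER_CONTROL = "leader_control"
    COMPROMISE = "compromise"
    FOLLOWER_CONTROL = "follower_control"
    DEGENERATE_CONTINUUM = "degenerate_continuum"


@dataclass(frozen=True)
class AnalyticEquilibrium:
    """Closed-form equilibrium plus regime label and omega thresholds.

    ``omega_lower``/``omega_upper`` bound the compromise window; either may
    exceed 1 (that part of the window is unreachable for valid omega) or be
    infinite when a preference sits at an extreme.  In the degenerate
    continuum only ``p_group_star`` is determinate and the class strategies
    are NaN.
    """

    p_leader_star: float
    p_follower_star: float
    p_group_star: float
    regime: Regime
    omega_lower: float
    omega_upper: float
    vtilde_leader: float
    vtilde_follower: float

    @property
    def strategies_determinate(self) -> bool:
        return self.regime is not Regime.DEGENERATE_CONTINUUM


def _preferences(payoffs: ClassPayoffs) -> Tuple[float, float]:
    return payoffs.preference_leader, payoffs.preference_follower


def _is_degenerate(vt_l: float, vt_f: float) -> bool:
    return abs(vt_l - vt_f) <= DEGENERACY_RTOL * max(abs(vt_l), abs(vt_f), 1.0)


def _ratio(num: float, den: float) -> float:
    """num/den with the +inf limit when den = 0 (num > 0 there)."""
    if den == 0.0:
        return math.inf
    return num / den


def regime_thresholds(
    payoffs: ClassPayoffs, epsilon: float
) -> Tuple[float, float]:
    """Omega thresholds bounding the compromise window.

    For leader-advantaged societies the window is
    ``[eps (1 - vt_L) / ((1 - eps) vt_L), eps (1 - vt_F) / ((1 - eps) vt_F)]``;
    for follower-advantaged ones,
    ``[eps vt_L / ((1 - eps) (1 - vt_L)), eps vt_F / ((1 - eps) (1 - vt_F))]``.
    Values above 1 are returned as-is (that control regime is unreachable
    for valid omega); a preference at an extreme yields the 0 or +inf
    limit.

    Raises
    ------
    DegenerateRegimeError
        When the clamped preferences coincide.
    """
    vt_l, vt_f = _preferences(payoffs)
    if _is_degenerate(vt_l, vt_f):
        raise DegenerateRegimeError(
            f"class preferences coincide (vt = {vt_l}); the regime "
            "thresholds are undefined on the equilibrium continuum"
        )
    r = epsilon / (1.0 - epsilon)
    if vt_l > vt_f:
        lower = _ratio(r * (1.0 - vt_l), vt_l)
        upper = _ratio(r * (1.0 - vt_f), vt_f)
    else:
        lower = _ratio(r * vt_l, 1.0 - vt_l)
        upper = _ratio(r * vt_f, 1.0 - vt_f)
    return lower, upper


def solve_equilibrium(
    config: ModelConfig, payoffs: Optional[ClassPayoffs] = None
) -> AnalyticEquilibrium:
    """Evaluate the piecewise closed-form equilibrium for one society."""
    if payoffs is None:
        payoffs = class_payoffs(config)
    vt_l, vt_f = _preferences(payoffs)
    eps = config.epsilon
    om = config.omega
    infl = config.influence

    if _is_degenerate(vt_l, vt_f):
        return AnalyticEquilibrium(
            p_leader_star=math.nan,
            p_follower_star=math.nan,
            p_group_star=vt_l,
            regime=Regime.DEGENERATE_CONTINUUM,
            omega_lower=math.nan,
            omega_upper=math.nan,
            vtilde_leader=payoffs.vtilde_leader,
            vtilde_follower=payoffs.vtilde_follower,
        )

    lower, upper = regime_thresholds(payoffs, eps)
    leader_advantaged = vt_l > vt_f

    if leader_advantaged:
        if om < lower:
            regime = Regime.LEADER_CONTROL
            pl = vt_l * (eps + (1.0 - eps) * om) / eps
            pf = 0.0
            pg = vt_l
        elif om <= upper:
            regime = Regime.COMPROMISE
            pl, pf = 1.0, 0.0
            pg = eps / infl
        else:
            regime = Regime.FOLLOWER_CONTROL
            pl = 1.0
            pf = vt_f - (eps / ((1.0 - eps) * om)) * (1.0 - vt_f)
            pg = vt_f
    else:
        if om < lower:
            regime = Regime.LEADER_CONTROL
            pl = vt_l - ((1.0 - eps) * om / eps) * (1.0 - vt_l)
            pf = 1.0
            pg = vt_l
        elif om <= upper:
            regime = Regime.COMPROMISE
            pl, pf = 0.0, 1.0
            pg = om * (1.0 - eps) / infl
        else:
            regime = Regime.FOLLOWER_CONTROL
            pl = 0.0
            pf = vt_f * infl / (om * (1.0 - eps))
            pg = vt_f

    return AnalyticEquilibrium(
        p_leader_star=pl,
        p_follower_star=pf,
        p_group_star=pg,
        regime=regime,
        omega_lower=lower,
        omega_upper=upper,
        vtilde_leader=payoffs.vtilde_leader,
        vtilde_follower=payoffs.vtilde_follower,
    )


def classify_regime(
    config: ModelConfig, payoffs: Optional[ClassPayoffs] = None
) -> Regime:
    """Regime label only — a pure function of (vt_L, vt_F, eps, omega)."""
    return solve_equilibrium(config, payoffs).regime
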
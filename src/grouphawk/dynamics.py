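"""Mutant payoff, selection gradients, and numerical integration of the
adaptive dynamics on the unit square.

Evolution is modelled by adaptive dynamics: the population is monomorphic
for a strategy (P_L, P_F) and evolves along the fitness gradient of rare
mutants of small effect.  The gradient components are

    dP_L/dt = eps (V_L - P C_L) / (2 N (eps + omega (1 - eps)))
    dP_F/dt = omega (1 - eps) (V_F - P C_F) / (2 N (eps + omega (1 - eps)))

so each class is pushed toward states where the collective P matches its
own preference V_i/C_i, with a speed diluted by group size (one voice among
N) and, for followers, by the sharing weight omega.  Strategies are
probabilities, so the flow is clamped to [0, 1]^2 by projection: an outward
gradient component at a face is zeroed, which is what lets equilibria sit
at the obligate extremes 0 and 1.

The interior vector field is affine in (P_L, P_F) through P alone — its
Jacobian is rank one with a single non-zero (negative) eigenvalue — so a
projected explicit Euler scheme with a step chosen from that eigenvalue is
both stable and monotone; no stiff machinery is needed.  Correctness is
anchored to the closed-form solution (see ``grouphawk.equilibrium``), not
to integrator sophistication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .payoffs import ClassPayoffs, ModelConfig, StrategyPair, class_payoffs

__all__ = [
    "GradientVector",
    "Trajectory",
    "mutant_payoff",
    "selection_gradient",
    "integrate_to_equilibrium",
]


@dataclass(frozen=True)
class GradientVector:
    """Rates of evolutionary change of the two strategy components."""

    dp_leader: float
    dp_follower: float

    @property
    def norm(self) -> float:
        return math.hypot(self.dp_leader, self.dp_follower)


def mutant_payoff(
    mutant_p_leader: float,
    mutant_p_follower: float,
    resident: StrategyPair,
    config: ModelConfig,
    payoffs: Optional[ClassPayoffs] = None,
) -> float:
    """Expected payoff to a rare mutant in a resident population.

    The mutant's group plays Hawk with the perturbed probability Q_L (if
    the mutant is drawn as a leader, probability eps) or Q_F (follower,
    probability 1 - eps); the opposing group of residents plays Hawk with
    probability P.  Encounter outcomes follow the Hawk-Dove rules with
    per-capita class payoffs: an escalated fight yields (V_i - C_i)/2 in
    expectation, Hawk vs Dove takes V_i, Dove vs Dove splits V_i/2, and
    conceding yields 0.
    """
    if payoffs is None:
        payoffs = class_payoffs(config)
    from .payoffs import mutant_group_hawk_probability

    p = resident.p_group
    eps = config.epsilon
    w = 0.0
    for role, mutant_p, v_i, c_i, weight in (
        ("leader", mutant_p_leader, payoffs.v_leader, payoffs.c_leader, eps),
        ("follower", mutant_p_follower, payoffs.v_follower, payoffs.c_follower, 1.0 - eps),
    ):
        q = mutant_group_hawk_probability(resident, mutant_p, role, config)
        w += weight * (
            q * p * (v_i - c_i) / 2.0
            + q * (1.0 - p) * v_i
            + (1.0 - q) * (1.0 - p) * v_i / 2.0
        )
    return w


def selection_gradient(
    resident: StrategyPair,
    config: ModelConfig,
    payoffs: Optional[ClassPayoffs] = None,
) -> GradientVector:
    """Partial derivatives of mutant payoff at the resident strategy."""
    if payoffs is None:
        payoffs = class_payoffs(config)
    p = resident.p_group
    eps = config.epsilon
    scale = 2.0 * config.n_group * config.influence
    return GradientVector(
        dp_leader=eps * (payoffs.v_leader - p * payoffs.c_leader) / scale,
        dp_follower=config.omega
        * (1.0 - eps)
        * (payoffs.v_follower - p * payoffs.c_follower)
        / scale,
    )


@dataclass
class Trajectory:
    """Recorded flow of the clamped adaptive dynamics.

    ``converged`` is True when the projected-gradient norm stayed below the
    tolerance for a sustained window of steps; ``follower_neutral`` flags
    the omega = 0 degeneracy in which the follower component feels no
    selection at all and simply retains its initial value.
    """

    times: np.ndarray
    p_leader: np.ndarray
    p_follower: np.ndarray
    p_group: np.ndarray
    converged: bool
    iterations: int
    follower_neutral: bool = False
    config: Optional[ModelConfig] = field(default=None, repr=False)

    @property
    def equilibrium(self) -> StrategyPair:
        """Final state of the flow (the equilibrium when ``converged``)."""
        return StrategyPair(
            p_leader=float(self.p_leader[-1]),
            p_follower=float(self.p_follower[-1]),
            p_group=float(self.p_group[-1]),
        )

    @property
    def states(self) -> Sequence[StrategyPair]:
        return [
            StrategyPair(float(pl), float(pf), float(pg))
            for pl, pf, pg in zip(self.p_leader, self.p_follower, self.p_group)
        ]


def _projected(g: float, x: float) -> float:
    """Zero an outward gradient component at the faces of [0, 1]."""
    if (x <= 0.0 and g < 0.0) or (x >= 1.0 and g > 0.0):
        return 0.0
    return g


def integrate_to_equilibrium(
    initial: StrategyPair,
    config: ModelConfig,
    *,
    payoffs: Optional[ClassPayoffs] = None,
    grad_tol: float = 1e-10,
    window: int = 100,
    max_time: Optional[float] = None,
    max_step_displacement: float = 0.02,
    record: bool = True,
) -> Trajectory:
    """Integrate the clamped gradient flow from ``initial`` to rest.

    Convergence is declared when the projected-gradient norm stays below
    ``grad_tol`` for ``window`` consecutive accepted steps, which
    distinguishes genuine arrival from slow transit near a nullcline.  If
    ``max_time`` (default: 5000 relaxation times of the interior flow) is
    exhausted first, the trajectory is returned with ``converged=False``
    rather than raising.
    """
    if payoffs is None:
        payoffs = class_payoffs(config)
    eps = config.epsilon
    om = config.omega
    infl = config.influence
    scale = 2.0 * config.n_group * infl
    a_l = eps / scale
    a_f = om * (1.0 - eps) / scale
    w_l = eps / infl
    w_f = om * (1.0 - eps) / infl
    # Single non-zero Jacobian eigenvalue of the interior (rank-1) field.
    lam = a_l * payoffs.c_leader * w_l + a_f * payoffs.c_follower * w_f
    if lam <= 0.0:
        raise ConfigError("degenerate vector field: zero contraction rate")
    dt_stable = 0.5 / lam
    if max_time is None:
        max_time = 5000.0 / lam

    pl = float(initial.p_leader)
    pf = float(initial.p_follower)
    t = 0.0
    streak = 0
    converged = False
    iterations = 0
    times = [t]
    pls = [pl]
    pfs = [pf]

    def group_p(pl: float, pf: float) -> float:
        return (pl * eps + pf * om * (1.0 - eps)) / infl

    while t < max_time:
        p = group_p(pl, pf)
        g_l = a_l * (payoffs.v_leader - p * payoffs.c_leader)
        g_f = a_f * (payoffs.v_follower - p * payoffs.c_follower)
        pg_l = _projected(g_l, pl)
        pg_f = _projected(g_f, pf)
        if math.hypot(pg_l, pg_f) < grad_tol:
            streak += 1
            if streak >= window:
                converged = True
                break
        else:
            streak = 0
        g_max = max(abs(g_l), abs(g_f))
        dt = dt_stable if g_max == 0.0 else min(dt_stable, max_step_displacement / g_max)
        pl = min(max(pl + dt * g_l, 0.0), 1.0)
        pf = min(max(pf + dt * g_f, 0.0), 1.0)
        t += dt
        iterations += 1
        if record:
            times.append(t)
            pls.append(pl)
            pfs.append(pf)

    if not record:
        times = [0.0, t]
        pls = [float(initial.p_leader), pl]
        pfs = [float(initial.p_follower), pf]
    times_arr = np.asarray(times)
    pl_arr = np.asarray(pls)
    pf_arr = np.asarray(pfs)
    pg_arr = (pl_arr * eps + pf_arr * om * (1.0 - eps)) / infl
    return Trajectory(
        times=times_arr,
        p_leader=pl_arr,
        p_follower=pf_arr,
        p_group=pg_arr,
        converged=converged,
        iterations=iterations,
        follower_neutral=(a_f == 0.0),
        config=config,
    )
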
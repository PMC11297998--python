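"""Model parameters, cost/benefit sharing rules, and the collective
decision rule.

A society is described by seven parameters: a group of ``n_group``
individuals contains a fraction ``epsilon`` of leaders; a contested
resource is worth ``v_total`` to the winning group and an escalated fight
costs the losing group ``c_total`` (with ``c_total > v_total``, the
classic mixed-strategy condition of the Hawk-Dove game).  The benefit and
cost are divided between the two classes according to the biases ``d_v``
and ``d_c`` (0.5 = equal per-capita shares; values above 0.5 advantage
leaders).  Each individual carries two heritable Hawk probabilities, one
per role, and group votes are pooled into a single collective Hawk
probability with follower votes down-weighted by ``omega`` (0 = unshared,
leader-dictated decisions; 1 = fully shared, one-individual-one-vote).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .errors import (
    ConfigError,
    DegenerateDivisionError,
    InvalidPerturbationError,
    UndefinedDecisionError,
)

__all__ = [
    "ModelConfig",
    "ClassPayoffs",
    "StrategyPair",
    "class_payoffs",
    "collective_hawk_probability",
    "mutant_group_hawk_probability",
]

#: Probabilities may exit [0, 1] by at most this much before it is treated
#: as a logic error rather than floating-point round-off.
CLAMP_TOL = 1e-12


def _clamp_unit(x: float, *, what: str = "probability") -> float:
    """Clamp ``x`` into [0, 1], tolerating only round-off excursions."""
    if x < -CLAMP_TOL or x > 1.0 + CLAMP_TOL:
        raise InvalidPerturbationError(
            f"{what} = {x!r} lies outside [0, 1] beyond round-off tolerance"
        )
    return min(max(x, 0.0), 1.0)


@dataclass(frozen=True)
class ModelConfig:
    """The seven fixed parameters defining one society.

    Parameters
    ----------
    omega
        Decision-sharing weight of a follower's vote relative to a
        leader's, in [0, 1].
    epsilon
        Proportion of each group assigned the leader role, in (0, 1).
        ``epsilon = 1`` is rejected; the all-leader limit is recovered as
        ``omega = 0`` behaviour instead.
    n_group
        Group size N (>= 2).
    v_total
        Collective benefit V of winning an encounter (> 0).
    c_total
        Collective cost C paid by the losing group of an escalated fight
        (> v_total).
    d_v, d_c
        Division biases in [0, 1] controlling how V and C are split
        between leaders and followers (0.5 = equal per-capita shares).
    """

    omega: float
    epsilon: float
    n_group: int
    v_total: float = 1.0
    c_total: float = 2.0
    d_v: float = 0.5
    d_c: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ConfigError(f"omega must lie in [0, 1], got {self.omega}")
        if not 0.0 < self.epsilon < 1.0:
            raise ConfigError(
                f"epsilon must lie in the open interval (0, 1), got {self.epsilon}"
            )
        if int(self.n_group) != self.n_group or self.n_group < 2:
            raise ConfigError(f"n_group must be an integer >= 2, got {self.n_group}")
        if not self.v_total > 0.0:
            raise ConfigError(f"v_total must be positive, got {self.v_total}")
        if not self.c_total > self.v_total:
            raise ConfigError(
                f"c_total must exceed v_total (got C={self.c_total}, V={self.v_total})"
            )
        for name in ("d_v", "d_c"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {val}")

    @property
    def influence(self) -> float:
        """Total decision weight epsilon + omega * (1 - epsilon)."""
        return self.epsilon + self.omega * (1.0 - self.epsilon)

    @property
    def n_leaders_exact(self) -> float:
        return self.epsilon * self.n_group

    def require_integer_leaders(self) -> int:
        """Return epsilon * n_group as an integer, or raise.

        The analytic theory treats epsilon as continuous; the
        individual-based simulation needs a whole number of leaders per
        group and enforces this strictly.
        """
        n_leaders = self.epsilon * self.n_group
        if abs(n_leaders - round(n_leaders)) > 1e-9:
            raise ConfigError(
                f"epsilon * n_group = {n_leaders} is not an integer; the "
                "individual-based simulation requires a whole number of "
                "leaders per group"
            )
        return int(round(n_leaders))

    def with_(self, **changes) -> "ModelConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ClassPayoffs:
    """Per-capita costs/benefits of each class and the induced preferences.

    ``vtilde_leader = v_leader / c_leader`` is the Hawk probability leaders
    would install if they alone controlled the group (the single-class
    Hawk-Dove ESS), and likewise for followers.  Skewed division biases can
    push a raw ratio above 1, in which case the class's realisable
    preference saturates at obligate Hawk (probability 1); the raw ratio is
    kept and ``preference_*`` exposes the clamped value.
    """

    c_leader: float
    c_follower: float
    v_leader: float
    v_follower: float
    vtilde_leader: float
    vtilde_follower: float

    @property
    def preference_leader(self) -> float:
        """Leader preference clamped into [0, 1] (obligate Hawk above 1)."""
        return min(self.vtilde_leader, 1.0)

    @property
    def preference_follower(self) -> float:
        return min(self.vtilde_follower, 1.0)

    @property
    def obligate_hawk_leader(self) -> bool:
        """True when the raw leader preference exceeds 1 (always-Hawk)."""
        return self.vtilde_leader > 1.0

    @property
    def obligate_hawk_follower(self) -> bool:
        return self.vtilde_follower > 1.0


def class_payoffs(config: ModelConfig) -> ClassPayoffs:
    """Evaluate the sharing rules for one society.

    The collective cost C is split so that a leader pays
    ``C (1 - d_c) / (N (d_c (1 - eps) + eps (1 - d_c)))`` and a follower
    ``C d_c / (same denominator)``; the benefit V is split analogously with
    ``d_v`` favouring leaders.  Group totals always reconstruct C and V
    exactly (a property the test-suite asserts over random societies).

    Raises
    ------
    DegenerateDivisionError
        If ``d_c`` is 0 or 1, which zeroes one class's per-capita cost and
        leaves its preference V_i/C_i undefined.
    """
    if config.d_c in (0.0, 1.0):
        raise DegenerateDivisionError(
            f"d_c = {config.d_c} puts zero cost on one class; the class "
            "preference V_i/C_i is undefined"
        )
    eps = config.epsilon
    n = config.n_group
    dc, dv = config.d_c, config.d_v
    cost_denom = n * (dc * (1.0 - eps) + eps * (1.0 - dc))
    benefit_denom = n * (eps * dv + (1.0 - dv) * (1.0 - eps))
    c_leader = config.c_total * (1.0 - dc) / cost_denom
    c_follower = config.c_total * dc / cost_denom
    v_leader = config.v_total * dv / benefit_denom
    v_follower = config.v_total * (1.0 - dv) / benefit_denom
    return ClassPayoffs(
        c_leader=c_leader,
        c_follower=c_follower,
        v_leader=v_leader,
        v_follower=v_follower,
        vtilde_leader=v_leader / c_leader,
        vtilde_follower=v_follower / c_follower,
    )


def collective_hawk_probability(
    p_leader_mean: float,
    p_follower_mean: float,
    omega: float,
    epsilon: float,
) -> float:
    """Pool class mean votes into the group's collective Hawk probability.

    Returns ``(Pbar_L eps + Pbar_F omega (1 - eps)) / (eps + omega (1 - eps))``
    — a convex combination of the two class means, sliding from pure leader
    control at omega = 0 to the plain population mean at omega = 1.
    """
    for name, p in (("p_leader_mean", p_leader_mean), ("p_follower_mean", p_follower_mean)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {p}")
    if not 0.0 <= omega <= 1.0:
        raise ConfigError(f"omega must lie in [0, 1], got {omega}")
    if not 0.0 <= epsilon <= 1.0:
        raise ConfigError(f"epsilon must lie in [0, 1], got {epsilon}")
    denom = epsilon + omega * (1.0 - epsilon)
    if denom == 0.0:
        raise UndefinedDecisionError(
            "epsilon = 0 and omega = 0 leave no individual with any influence"
        )
    p = (p_leader_mean * epsilon + p_follower_mean * omega * (1.0 - epsilon)) / denom
    return _clamp_unit(p, what="collective Hawk probability")


@dataclass(frozen=True)
class StrategyPair:
    """A resident strategy (P_L, P_F) with its induced collective P."""

    p_leader: float
    p_follower: float
    p_group: float

    def __post_init__(self) -> None:
        for name in ("p_leader", "p_follower", "p_group"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {val}")

    @classmethod
    def from_class_strategies(
        cls, p_leader: float, p_follower: float, config: ModelConfig
    ) -> "StrategyPair":
        """Build a pair, deriving the collective P from the pooling rule."""
        return cls(
            p_leader=p_leader,
            p_follower=p_follower,
            p_group=collective_hawk_probability(
                p_leader, p_follower, config.omega, config.epsilon
            ),
        )


def mutant_group_hawk_probability(
    resident: StrategyPair,
    mutant_p: float,
    role: Literal["leader", "follower"],
    config: ModelConfig,
) -> float:
    """Collective Hawk probability of a group containing one focal mutant.

    A single deviant shifts its group's pooled vote by its own weight:
    ``Q_L = P + (P'_L - P_L) / (N (eps + omega (1 - eps)))`` when the focal
    individual is drawn as a leader, and
    ``Q_F = P + omega (P'_F - P_F) / (N (eps + omega (1 - eps)))`` as a
    follower.  Either perturbation is O(1/N): one voice among N.
    """
    if not 0.0 <= mutant_p <= 1.0:
        raise ConfigError(f"mutant_p must lie in [0, 1], got {mutant_p}")
    denom = config.n_group * config.influence
    if role == "leader":
        q = resident.p_group + (mutant_p - resident.p_leader) / denom
    elif role == "follower":
        q = resident.p_group + config.omega * (mutant_p - resident.p_follower) / denom
    else:
        raise ValueError(f"role must be 'leader' or 'follower', got {role!r}")
    return _clamp_unit(q, what=f"mutant group Hawk probability ({role})")
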
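"""Individual-based mutation-selection simulation of the collective
Hawk-Dove game.

The analytic theory assumes an infinite monomorphic population evolving by
small mutational steps.  This module checks that those equilibria are
actually reachable by evolution in a finite polymorphic population with an
explicit life cycle (Wright-Fisher style, non-overlapping generations):

1. the M*N individuals are shuffled into M groups of N;
2. within each group, eps*N random members act as leaders this generation;
3. each group's collective Hawk probability pools the mean leader gene and
   mean follower gene of its current members;
4. groups are paired and each pair realises ``encounters_per_generation``
   independent Hawk/Dove encounters (Dove-Dove splits V; Hawk takes V from
   Dove; Hawk-Hawk picks a loser by fair coin, which pays C), with each
   group's take divided per-capita between its classes by the sharing
   rules and summed over encounters;
5. the next generation is sampled with replacement in proportion to
   fitness — by default an exponential (Boltzmann) weighting
   ``exp(selection_strength * payoff)``, normalised within each role class
   so classes reproduce in proportion to their shares (a linear
   ``selection_baseline + payoff`` weighting is also available);
6. each gene (the Hawk probabilities as leader and as follower) mutates
   independently with probability ``mutation_rate`` by a zero-mean
   Gaussian kick of sd ``mutation_sd``, reflected into [0, 1].

Selection on a single gene is weak by construction — one voice among N,
diluted again by omega for followers — so many encounters per generation
are used to average the group-shared outcome noise; the expected payoff
(and hence the selection gradient) scales with the number of encounters
while the noise grows only as its square root.  See docs/methods.md for
the mixing-time reasoning behind the defaults and for why fitness is
normalised within role classes (roles are transient per-encounter
properties in the theory; letting a whole generation's frozen role
assignment skew class reproductive shares would inject a between-class
selection component the model does not contain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .equilibrium import AnalyticEquilibrium
from .errors import ConfigError, GroupHawkError
from .payoffs import ClassPayoffs, ModelConfig, class_payoffs

__all__ = [
    "SimConfig",
    "Population",
    "SimResult",
    "ComparisonRecord",
    "run_generation",
    "run_simulation",
    "summarize",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters around a :class:`ModelConfig`.

    ``selection_baseline`` is the constant added to every accumulated
    payoff before fitness-proportional sampling; it must exceed C/N so no
    single escalated loss can drive fitness negative.  ``None`` selects
    2 C / N.
    """

    model: ModelConfig
    pop_groups: int = 500
    encounters_per_generation: int = 6400
    mutation_sd: float = 0.01
    mutation_rate: float = 0.03
    generations: int = 6000
    burn_in: int = 3000
    seed: int = 0
    selection: str = "exponential"
    selection_strength: Optional[float] = None
    selection_baseline: Optional[float] = None

    def __post_init__(self) -> None:
        self.model.require_integer_leaders()
        if self.pop_groups < 2 or self.pop_groups % 2 != 0:
            raise ConfigError(
                f"pop_groups must be even and >= 2 (groups are paired), got {self.pop_groups}"
            )
        if self.encounters_per_generation < 1:
            raise ConfigError("encounters_per_generation must be >= 1")
        if not self.mutation_sd > 0.0:
            raise ConfigError(f"mutation_sd must be positive, got {self.mutation_sd}")
        if not 0.0 < self.mutation_rate <= 1.0:
            raise ConfigError(
                f"mutation_rate must lie in (0, 1], got {self.mutation_rate}"
            )
        if not self.generations > self.burn_in >= 0:
            raise ConfigError(
                f"need generations > burn_in >= 0, got {self.generations}, {self.burn_in}"
            )
        if self.selection not in ("exponential", "linear"):
            raise ConfigError(
                f"selection must be 'exponential' or 'linear', got {self.selection!r}"
            )
        if self.selection == "linear" and self.baseline <= self.model.c_total / self.model.n_group:
            raise ConfigError(
                f"selection_baseline = {self.baseline} must exceed C/N = "
                f"{self.model.c_total / self.model.n_group} to rule out negative fitness"
            )
        if not self.strength > 0.0:
            raise ConfigError(f"selection_strength must be positive, got {self.strength}")

    @property
    def baseline(self) -> float:
        if self.selection_baseline is None:
            return 2.0 * self.model.c_total / self.model.n_group
        return self.selection_baseline

    @property
    def strength(self) -> float:
        """Exponential selection intensity (inverse payoff units).

        The default scales as N / V, which makes the per-encounter
        log-fitness increments scale-free (per-capita payoffs are O(V/N)).
        The prefactor balances per-generation selection against the
        group-shared fitness noise of the realised encounter outcomes; see
        docs/methods.md for the reasoning.
        """
        if self.selection_strength is None:
            return 0.0024 * self.model.n_group / self.model.v_total
        return self.selection_strength

    @property
    def pop_size(self) -> int:
        return self.pop_groups * self.model.n_group


@dataclass
class Population:
    """Gene arrays of the whole population (one row per individual)."""

    gene_leader: np.ndarray
    gene_follower: np.ndarray

    @classmethod
    def uniform(cls, pop_size: int, rng: np.random.Generator) -> "Population":
        """Maximal standing variation: genes i.i.d. uniform on [0, 1]."""
        return cls(
            gene_leader=rng.random(pop_size),
            gene_follower=rng.random(pop_size),
        )


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect values into [0, 1] (repeated folding handles big kicks)."""
    x = np.abs(x)
    while np.any(x > 1.0):
        x = np.where(x > 1.0, 2.0 - x, x)
        x = np.abs(x)
    return x


def _encounter_payoffs(
    hawk_a: np.ndarray,
    hawk_b: np.ndarray,
    coin_a_wins: np.ndarray,
    payoffs: ClassPayoffs,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-capita class payoffs of paired groups for realised choices.

    Returns (leader_a, follower_a, leader_b, follower_b) per-capita
    payoffs.  Hawk-Hawk escalates: the coin decides which group loses C;
    Hawk vs Dove takes the whole V; Dove-Dove splits it.
    """
    shape = np.broadcast_shapes(hawk_a.shape, hawk_b.shape)
    out = [np.zeros(shape) for _ in range(4)]
    pay_l_a, pay_f_a, pay_l_b, pay_f_b = out

    both_hawk = hawk_a & hawk_b
    a_only = hawk_a & ~hawk_b
    b_only = ~hawk_a & hawk_b
    neither = ~hawk_a & ~hawk_b

    v_l, v_f = payoffs.v_leader, payoffs.v_follower
    c_l, c_f = payoffs.c_leader, payoffs.c_follower

    a_wins = both_hawk & coin_a_wins
    b_wins = both_hawk & ~coin_a_wins
    pay_l_a[a_wins] = v_l
    pay_f_a[a_wins] = v_f
    pay_l_b[a_wins] = -c_l
    pay_f_b[a_wins] = -c_f
    pay_l_a[b_wins] = -c_l
    pay_f_a[b_wins] = -c_f
    pay_l_b[b_wins] = v_l
    pay_f_b[b_wins] = v_f

    pay_l_a[a_only] = v_l
    pay_f_a[a_only] = v_f
    pay_l_b[b_only] = v_l
    pay_f_b[b_only] = v_f

    pay_l_a[neither] = v_l / 2.0
    pay_f_a[neither] = v_f / 2.0
    pay_l_b[neither] = v_l / 2.0
    pay_f_b[neither] = v_f / 2.0
    return pay_l_a, pay_f_a, pay_l_b, pay_f_b


def run_generation(
    state: Population,
    sim: SimConfig,
    rng: np.random.Generator,
    payoffs: Optional[ClassPayoffs] = None,
) -> Tuple[Population, dict]:
    """Advance the population by one full life cycle.

    Returns the next generation and a summary dict with the population
    mean genes and the collective Hawk probability they imply.
    """
    if payoffs is None:
        payoffs = class_payoffs(sim.model)
    model = sim.model
    n = model.n_group
    m = sim.pop_groups
    n_lead = model.require_integer_leaders()
    pop = sim.pop_size
    eps, om = model.epsilon, model.omega
    infl = model.influence

    # (1)-(2) shuffle into groups; first n_lead slots of each row lead.
    perm = rng.permutation(pop)
    g_l = state.gene_leader[perm].reshape(m, n)
    g_f = state.gene_follower[perm].reshape(m, n)
    mean_lead = g_l[:, :n_lead].mean(axis=1)
    mean_foll = g_f[:, n_lead:].mean(axis=1)

    # (3) each group's collective Hawk probability (pooled vote).
    p_group = (mean_lead * eps + mean_foll * om * (1.0 - eps)) / infl

    # (4) paired encounters; payoffs accumulate per (group, class).  Group
    # composition is re-randomised by the shuffle in (1), so pairing group
    # 2i with 2i+1 is already random with respect to genes; each pair then
    # realises k independent encounters.  The k outcomes are iid, so their
    # category counts (escalated / one-sided / peaceful, and the coin flips
    # of escalated fights) are the sufficient statistic, drawn here as one
    # multinomial + binomial per pair instead of k per-encounter draws.
    k = sim.encounters_per_generation
    half = m // 2
    a = np.arange(0, m, 2)
    b = np.arange(1, m, 2)
    p_a, p_b = p_group[a], p_group[b]
    p_hh = p_a * p_b
    p_ah = p_a * (1.0 - p_b)
    p_bh = (1.0 - p_a) * p_b
    p_dd = np.clip(1.0 - p_hh - p_ah - p_bh, 0.0, 1.0)
    counts = rng.multinomial(k, np.column_stack([p_hh, p_ah, p_bh, p_dd]))
    n_hh, n_ah, n_bh, n_dd = counts.T
    n_aw = rng.binomial(n_hh, 0.5)  # escalated fights won by group a
    n_bw = n_hh - n_aw

    acc_lead = np.empty(m)
    acc_foll = np.empty(m)
    for cls_v, cls_c, acc in (
        (payoffs.v_leader, payoffs.c_leader, acc_lead),
        (payoffs.v_follower, payoffs.c_follower, acc_foll),
    ):
        acc[a] = cls_v * (0.5 * n_dd + n_ah + n_aw) - cls_c * n_bw
        acc[b] = cls_v * (0.5 * n_dd + n_bh + n_bw) - cls_c * n_aw

    # (5) fitness-weighted resampling of M*N offspring.  Roles are
    # transient: the theory assigns them afresh for every encounter, so an
    # individual's lifetime payoff weights the two roles by eps/(1 - eps).
    # Freezing roles for a whole generation would otherwise let the realised
    # between-class payoff gap skew class reproductive shares — a selection
    # component absent from the model — so fitness is normalised within
    # each role class and classes reproduce in proportion to their shares.
    if sim.selection == "exponential":
        w_lead = np.exp(sim.strength * (acc_lead - acc_lead.max()))
        w_foll = np.exp(sim.strength * (acc_foll - acc_foll.max()))
    else:
        w_lead = sim.baseline + acc_lead
        w_foll = sim.baseline + acc_foll
        if np.any(w_lead <= 0.0) or np.any(w_foll <= 0.0):
            raise GroupHawkError(
                "negative fitness encountered; selection_baseline is mis-set "
                "for this payoff scale (accumulated losses exceeded it)"
            )
    fitness = np.empty((m, n))
    fitness[:, :n_lead] = (eps / (n_lead * w_lead.sum())) * w_lead[:, None]
    fitness[:, n_lead:] = ((1.0 - eps) / ((n - n_lead) * w_foll.sum())) * w_foll[:, None]
    fitness = fitness.ravel()
    # Stratified fitness-proportional resampling: one uniform per offspring
    # slot, stratified over [0, 1) so the searchsorted queries are ordered
    # (unbiased, slightly sub-multinomial offspring-number variance).
    cdf = np.cumsum(fitness)
    positions = (np.arange(pop) + rng.random(pop)) * (cdf[-1] / pop)
    parents = np.searchsorted(cdf, positions)
    child_l = g_l.ravel()[parents].copy()
    child_f = g_f.ravel()[parents].copy()

    # (6) reflected Gaussian mutation, per gene.
    for genes in (child_l, child_f):
        hit = rng.random(pop) < sim.mutation_rate
        n_hit = int(hit.sum())
        if n_hit:
            genes[hit] = _reflect_unit(
                genes[hit] + rng.normal(0.0, sim.mutation_sd, size=n_hit)
            )

    summary = {
        "mean_p_leader": float(state.gene_leader.mean()),
        "mean_p_follower": float(state.gene_follower.mean()),
        "mean_p_group": float(
            (state.gene_leader.mean() * eps + state.gene_follower.mean() * om * (1.0 - eps))
            / infl
        ),
    }
    return Population(gene_leader=child_l, gene_follower=child_f), summary


@dataclass
class SimResult:
    """Per-generation population means plus post-burn-in time averages.

    Standard errors come from batch means (20 batches of the post-burn-in
    trace), which absorbs the strong autocorrelation of the means.
    """

    mean_p_leader: np.ndarray
    mean_p_follower: np.ndarray
    mean_p_group: np.ndarray
    avg_p_leader: float
    avg_p_follower: float
    avg_p_group: float
    se_p_leader: float
    se_p_follower: float
    se_p_group: float
    seed: int
    config: SimConfig = field(repr=False)


def _batch_se(trace: np.ndarray, n_batches: int = 20) -> float:
    usable = (len(trace) // n_batches) * n_batches
    if usable < n_batches:
        return float("nan")
    batches = trace[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def run_simulation(sim: SimConfig) -> SimResult:
    """Run the full mutation-selection simulation (deterministic per seed)."""
    rng = np.random.default_rng(sim.seed)
    payoffs = class_payoffs(sim.model)
    state = Population.uniform(sim.pop_size, rng)
    traces = {k: np.empty(sim.generations) for k in ("mean_p_leader", "mean_p_follower", "mean_p_group")}
    for gen in range(sim.generations):
        state, summary = run_generation(state, sim, rng, payoffs)
        for key, val in summary.items():
            traces[key][gen] = val
    post = slice(sim.burn_in, None)
    return SimResult(
        mean_p_leader=traces["mean_p_leader"],
        mean_p_follower=traces["mean_p_follower"],
        mean_p_group=traces["mean_p_group"],
        avg_p_leader=float(traces["mean_p_leader"][post].mean()),
        avg_p_follower=float(traces["mean_p_follower"][post].mean()),
        avg_p_group=float(traces["mean_p_group"][post].mean()),
        se_p_leader=_batch_se(traces["mean_p_leader"][post]),
        se_p_follower=_batch_se(traces["mean_p_follower"][post]),
        se_p_group=_batch_se(traces["mean_p_group"][post]),
        seed=sim.seed,
        config=sim,
    )


@dataclass(frozen=True)
class ComparisonRecord:
    """Deviations of simulated time-averages from the analytic equilibrium."""

    dev_p_leader: float
    dev_p_follower: float
    dev_p_group: float
    se_p_leader: float
    se_p_follower: float
    se_p_group: float
    strategies_comparable: bool
    tolerance: float
    passed: bool


def summarize(
    result: SimResult,
    analytic: AnalyticEquilibrium,
    tolerance: float = 0.05,
) -> ComparisonRecord:
    """Compare a simulation's time-averages against the analytic solution.

    In the degenerate continuum only the collective P is compared (the
    class strategies are indeterminate there).  ``passed`` requires every
    comparable deviation to be below ``tolerance``.
    """
    model = result.config.model
    from .equilibrium import solve_equilibrium

    expected = solve_equilibrium(model)
    if (
        expected.regime != analytic.regime
        or abs(expected.p_group_star - analytic.p_group_star) > 1e-9
    ):
        raise ConfigError(
            "analytic equilibrium does not correspond to the simulated model config"
        )
    comparable = analytic.strategies_determinate
    dev_p = abs(result.avg_p_group - analytic.p_group_star)
    if comparable:
        dev_l = abs(result.avg_p_leader - analytic.p_leader_star)
        dev_f = abs(result.avg_p_follower - analytic.p_follower_star)
    else:
        dev_l = float("nan")
        dev_f = float("nan")
    passed = dev_p < tolerance
    if comparable:
        passed = passed and dev_l < tolerance and dev_f < tolerance
    return ComparisonRecord(
        dev_p_leader=dev_l,
        dev_p_follower=dev_f,
        dev_p_group=dev_p,
        se_p_leader=result.se_p_leader,
        se_p_follower=result.se_p_follower,
        se_p_group=result.se_p_group,
        strategies_comparable=comparable,
        tolerance=tolerance,
        passed=passed,
    )
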
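# grouphawk

Evolutionary game theory of intergroup conflict when groups — not
individuals — decide whether to fight.  `grouphawk` implements a
collective Hawk-Dove model for societies of leaders and followers:
each group member votes Hawk or Dove, votes pool into one collective
decision with follower votes weighted by a sharing parameter Ω
(0 = autocratic, 1 = democratic), and the spoils `V` and fight costs `C`
are divided unevenly between the classes.  It is aimed at behavioural
ecologists and evolutionary modellers asking when shared decision-making
pacifies intergroup relations ("democratic peace") and when it inflames
them ("democratic war").

## The model in brief

An individual's strategy is `(P_L, P_F)` — its Hawk probabilities as
leader and as follower.  With leader fraction ε, the group plays Hawk
with probability

```
P = (P̄_L ε + P̄_F Ω (1 − ε)) / (ε + Ω (1 − ε)).
```

Division biases `d_c`, `d_v` split the per-capita costs and benefits, so
each class has a preferred level of collective aggression — the
single-class Hawk-Dove ESS `Ṽ_i = V_i / C_i`.  Adaptive dynamics on
`(P_L, P_F)` yields a unique stable equilibrium, piecewise in Ω: the
collective outcome `P*` is held at `Ṽ_L` (leader control), slides between
the two preferences while both classes play obligate extremes
("loudest voice prevails" compromise), or is held at `Ṽ_F` (follower
control).  When leaders are the advantaged class, `P*(Ω)` is
non-increasing — more sharing, less aggression; when followers are
advantaged the direction reverses.

The package provides:

* `grouphawk.payoffs` — parameter validation, sharing rules, the pooled
  collective decision, single-mutant group perturbations;
* `grouphawk.equilibrium` — closed-form equilibria, Ω-thresholds, regime
  classification (including the `Ṽ_L = Ṽ_F` continuum);
* `grouphawk.dynamics` — mutant payoff, selection gradients, projected
  integration of the adaptive dynamics on the unit square;
* `grouphawk.simulation` — an individual-based Wright-Fisher
  mutation–selection simulation of the same game, used to confirm the
  equilibria are evolutionarily reachable;
* `grouphawk.sweep` + a `grouphawk` CLI — Ω-profiles and (Ω, ε) regime
  maps as CSV/JSON.

See `docs/methods.md` for assumptions, numerical choices, and the
reasoning behind the simulation defaults.

## Worked example

The standard parameterisation used throughout the docs: ε = 0.3,
C = 2V, d_c = d_v = 0.55 (leaders mildly advantaged), N = 100.

```
$ grouphawk solve --omega 0.4 --epsilon 0.3 --n-group 100 \
    --v-total 1 --c-total 2 --d-v 0.55 --d-c 0.55
{
 "p_leader_star": 1.0,
 "p_follower_star": 0.0,
 "p_group_star": 0.5172413793103449,
 "regime": "compromise",
 "omega_lower": 0.21878121878121862,
 "omega_upper": 0.5384615384615387,
 "vtilde_leader": 0.6620370370370372,
 "vtilde_follower": 0.4431818181818181
}
```

Reading this: leaders prefer collective aggression `Ṽ_L ≈ 0.662`,
followers `Ṽ_F ≈ 0.443`.  At Ω = 0.4 — inside the compromise window
(0.2188, 0.5385) — both classes sit at obligate extremes (leaders always
vote Hawk, followers always Dove) and the group fights with probability
`P* = ε/(ε + Ω(1−ε)) ≈ 0.517`, partway between the two preferences.
Below Ω ≈ 0.2188 leaders hold `P*` at their preferred 0.662; above
Ω ≈ 0.5385 the follower majority holds it at 0.443.

Numerical integration of the adaptive dynamics lands on the same point:

```
$ grouphawk integrate --omega 0.4 --epsilon 0.3 --n-group 100 \
    --d-v 0.55 --d-c 0.55 --initial 0.5,0.5
{
 "converged": true,
 "iterations": 129,
 "follower_neutral": false,
 "p_leader": 1.0,
 "p_follower": 0.0,
 "p_group": 0.5172413793103449
}
```

Profiles and regime maps as data:

```
$ grouphawk profile --epsilon 0.3 --n-group 100 --v-total 1 --c-total 2 \
    --d-v 0.55 --d-c 0.55 --out profile.csv        # P*(Ω) on 0:0.01:1
$ grouphawk regime-map --n-group 100 --v-total 1 --c-total 2 \
    --d-v 0.55 --d-c 0.55 --out map.csv            # (Ω, ε) regime map
```

The same operations are available as library calls
(`solve_equilibrium`, `integrate_to_equilibrium`, `equilibrium_profile`,
`regime_map`, `run_simulation`), and a TOML/JSON config file can replace
the flags (`--config society.toml`; flags override file values).

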
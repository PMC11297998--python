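# Methods

## The model

Two groups of `N` individuals meet over a contested resource worth `V` to
the winning group; if both escalate, the losing group pays a cost `C > V`.
Each group decides *collectively* whether to play Hawk or Dove.  A fraction
`ε ∈ (0, 1)` of each group's members hold the leader role; the rest follow.
An individual's heritable strategy is a pair `(P_L, P_F)`: its probability
of voting Hawk when cast as a leader and as a follower.  Votes pool into
the group's collective Hawk probability

    P = (P̄_L ε + P̄_F Ω (1 − ε)) / (ε + Ω (1 − ε)),

where the sharing weight `Ω ∈ [0, 1]` discounts a follower's vote relative
to a leader's: `Ω = 0` is an unshared (leader-dictated) consensus, `Ω = 1`
a fully shared one-individual-one-vote consensus.  Once decided, the whole
group abides by the decision.

Spoils and costs are divided between the classes by two bias parameters.
A leader pays `C_L = C(1 − d_c) / (N(d_c(1 − ε) + ε(1 − d_c)))` per capita
and receives `V_L = V d_v / (N(ε d_v + (1 − d_v)(1 − ε)))`; the follower
shares are the complements.  The group totals always reassemble to `C` and
`V` exactly (an algebraic identity the tests verify to 1e−12 over random
parameter sets).  `d = 0.5` means equal per-capita shares; `d > 0.5`
advantages leaders.  Each class's *preference* is the Hawk probability it
would install if it alone controlled the group — the single-class
Hawk-Dove ESS `Ṽ_i = V_i / C_i`.  Skewed divisions can push a raw ratio
above 1; the realisable preference then saturates at obligate Hawk, and
the solver clamps it to 1 before any branch logic (the selection gradient
for such a class is positive everywhere on `[0, 1]`).

## Evolutionary analysis

Evolution is modelled by adaptive dynamics: a monomorphic population,
rare mutants of small effect, and strategy change along the mutant fitness
gradient.  A single deviant shifts its group's pooled vote by its own
weight (`1/(N(ε + Ω(1 − ε)))` as a leader, `Ω/(N(ε + Ω(1 − ε)))` as a
follower), which yields the gradient components

    dP_L/dt = ε (V_L − P C_L) / (2N(ε + Ω(1 − ε)))
    dP_F/dt = Ω (1 − ε)(V_F − P C_F) / (2N(ε + Ω(1 − ε))).

Each class pushes the collective `P` toward its own preference.  When the
preferences differ, the nullclines cannot intersect in the interior, and
the unique stable equilibrium has at least one class at an extreme.  With
leaders advantaged (`Ṽ_L > Ṽ_F`) the equilibrium is piecewise in `Ω`:

* **leader control**, `Ω < ε(1 − Ṽ_L)/((1 − ε)Ṽ_L)`: `P* = Ṽ_L`, with
  leaders inflating their own strategy
  (`P_L* = Ṽ_L(ε + (1 − ε)Ω)/ε`) to anchor the outcome while followers
  play 0;
* **compromise**, between the thresholds: both classes pinned at the
  extremes `(P_L*, P_F*) = (1, 0)` — "loudest voice prevails" — and
  `P* = ε/(ε + Ω(1 − ε))` falls from `Ṽ_L` to `Ṽ_F` as sharing increases
  (democratic peace);
* **follower control**, `Ω > ε(1 − Ṽ_F)/((1 − ε)Ṽ_F)`: `P* = Ṽ_F`, with
  `P_F* = Ṽ_F − (ε/((1 − ε)Ω))(1 − Ṽ_F)` rising back toward `Ṽ_F` as
  leaders' relative influence fades.

The follower-advantaged case mirrors this with 0 and 1 swapped and
`P* = Ω(1 − ε)/(ε + Ω(1 − ε))` rising through the compromise window
(democratic war).  The compromise expression equals the adjacent control
value exactly at each threshold, so `P*(Ω)` is continuous; a tie at a
threshold classifies as compromise.  Thresholds above 1 simply mean that
regime is unreachable; a preference at an extreme produces the natural
0 or `+inf` limit.  When `Ṽ_L = Ṽ_F` (within relative 1e−12) the
nullclines coincide and a continuum of equilibria shares
`P = Ṽ`; only the collective probability is then determinate.  All
equilibrium quantities are scale-free in `V` (only `C/V` matters) and
independent of `N`; worked examples use `V = 1`.

`ε = 1` is rejected as a configuration: the sharing-rule denominators and
the thresholds degenerate there, and the all-leader limit is already
represented by `Ω = 0`.  The analytic modules treat `ε` as continuous;
only the simulation requires `εN` to be an integer.

## Numerical integration

The interior vector field is affine in `(P_L, P_F)` through `P` alone, so
its Jacobian is rank one with a single negative eigenvalue
`λ = (ε²C_L + Ω²(1 − ε)²C_F) / (2N(ε + Ω(1 − ε))²)`.  The integrator is a
projected explicit Euler scheme with step `0.5/λ` (further capped so no
component moves more than 0.02 per step), which is monotone and stable for
this field; boundary handling is projection — an outward gradient
component at a face of the unit square is zeroed, matching the obligate
extremes of the equilibria.  Convergence is declared when the
projected-gradient norm stays below `1e−10` for 100 consecutive steps
(distinguishing arrival from slow transit near a nullcline); the default
time budget is `5000/λ`, and exhausting it returns an unconverged
trajectory rather than raising.  At `Ω = 0` the follower component feels
no selection at all; it is reported as neutral and held at its initial
value rather than assigned a convention.  (The solver's closed form
reports `P_F* = 0` there, the `Ω → 0⁺` continuity limit in the
leader-advantaged case — an interpretation, flagged as such.)  The
common prefactor `1/(2N(ε + Ω(1 − ε)))` is kept verbatim rather than
normalised into the time units, so the implemented equations can be
audited term by term; time budgets scale with `N` to compensate.

Against the closed form, integration from random interior starts agrees
in `P*` to better than `1e−5` across randomized parameter sweeps (the
acceptance suite requires `1e−3` over 200 societies × 10 starts).

## The individual-based simulation

The simulation re-derives the equilibria without any of the analytic
machinery: a finite polymorphic population of `M·N` individuals, each
carrying the two genes `(P_L, P_F)`, evolving by Wright-Fisher
mutation–selection.  Per generation: individuals are shuffled into `M`
groups; `εN` random members of each group lead; each group's collective
Hawk probability pools its members' genes; groups are paired and each
pair realises `K` independent encounters with the Hawk-Dove payoff rules
(escalated fights pick the loser by fair coin); per-capita class payoffs
accumulate; the next generation is resampled in proportion to fitness and
every gene mutates with probability `mutation_rate` by a reflected
Gaussian kick of sd `mutation_sd`.  Initial genes are i.i.d. uniform on
`[0, 1]` — maximal, unbiased standing variation.

Selection on a single gene is necessarily weak: one vote among `N`
(diluted again by `Ω` for followers) applied to per-capita payoffs of
order `V/N`.  Four numerical design choices follow from that, each chosen
from the mixing-time analysis below rather than tuned by eye:

1. **Exponential fitness.**  Offspring are drawn in proportion to
   `exp(β · payoff)` (`selection_strength` `β`, default `0.0024 N/V`,
   which makes the per-encounter log-fitness increments scale-free).  A
   linear `baseline + payoff` weighting is available
   (`selection="linear"`), but positivity forces its baseline above the
   worst accumulated loss, capping the per-gene selection intensity near
   `1e−3` per generation — recovering the equilibria to 0.05 would then
   need populations of order 10⁶.  Exponential weighting decouples
   intensity from positivity.
2. **Many encounters, drawn by sufficient statistics.**  The `K`
   encounter outcomes of a pair are i.i.d. given the two group
   probabilities, so the simulation draws their category counts as one
   multinomial (plus a binomial for the escalation coin flips) per pair.
   This makes `K` computationally free; the default `K = 6400` with the
   default `β` keeps the group-shared log-fitness noise near 0.15 —
   large shared noise would otherwise collapse the effective population
   size by a factor `≈ 1 + N·Σ²` and freeze the gene dynamics mid-transit.
3. **Within-class fitness normalisation.**  In the theory, roles are
   transient per-encounter properties, so every individual's lifetime
   payoff weights the two roles by `ε/(1 − ε)`.  The simulation freezes
   roles for one generation; letting the realised between-class payoff
   gap skew class reproductive shares would inject a between-class
   selection component the model does not contain (measurably suppressing
   follower-gene selection and inflating leader-gene selection relative
   to the adaptive-dynamics gradients).  Fitness is therefore normalised
   within each role class, and classes reproduce in proportion to their
   shares.
4. **Stratified resampling.**  Fitness-proportional sampling uses ordered
   stratified uniforms (as in particle filters): unbiased, slightly
   sub-multinomial offspring variance, and ~5× faster than generic
   weighted choice at these population sizes.

Mutation defaults (`rate 0.03`, `sd 0.01`) put the mutation diffusion
`rate·sd² ≈ 3e−6` per generation far below the selection slopes (so
mutation-selection boundary layers stay ~1e−3 wide and do not bias the
equilibria) while replenishing enough variance to keep the population
responsive.  Defaults `M = 500` groups (50,000 individuals), 6,000
generations with a 3,000-generation burn-in, were sized so that the
stationary wander of the population mean (`≈ sqrt(κ/(2·pop·s'))` for
restoring slope `s'`) stays well inside the 0.05 recovery tolerance;
a run takes roughly 25 s on one core.  Standard errors of the
post-burn-in time averages use 20 batch means, which absorbs the strong
autocorrelation of the traces.

What the simulation shows — and does not.  Against the closed form, the
time-averaged collective `P̄` lands within ~0.02 of `P*` in all three
regimes of the standard parameterisation, and class means approach the
obligate extremes up to mutation-selection layers (e.g. `P̄_L ≈ 0.95`
where `P_L* = 1`).  The generator emulates the model's own idealisation:
infinite well-mixed population, identical groups, no assortment, no
repeated interaction, binary roles.  Passing these checks says the
analytic equilibria are evolutionarily reachable under the model's
assumptions; it says nothing about heterogeneous real populations, group
structure that persists across generations, or co-evolution of `Ω` and
`ε`, all of which are outside scope.

## Degenerate and edge inputs

`d_c ∈ {0, 1}` zeroes one class's per-capita cost, leaving that class's
preference undefined; `class_payoffs` raises a degenerate-division error,
and sweeps record it per row instead of aborting.  `ε = 0` with `Ω = 0`
leaves no one any influence and is rejected.  Probability outputs may
exit `[0, 1]` only by round-off (1e−12); larger excursions raise, since
for valid inputs they indicate a mis-wired call rather than numerical
noise.

## Data products

`equilibrium_profile` tabulates `(P_L*, P_F*, P*, regime, thresholds)`
against `Ω` (default grid 0:0.01:1, which resolves the standard example's
thresholds ≈ 0.2188 and ≈ 0.5385 to two decimals); `regime_map` sweeps
`(Ω, ε)` with the payoff split recomputed at each `ε` (ε grid
0.01:0.01:0.99 — the endpoints are invalid societies) and returns
per-regime cell counts.  Writers emit CSV or JSON with floats at 12
significant digits; rendering figures from the CSV is left to the user's
plotting tool of choice.
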
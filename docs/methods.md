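# Methods

## Model

`coaware` couples two discrete-time spreading processes on a weighted
multiplex network of N nodes and M undirected layers sharing the node set.

**Contagion** is SIR-like: susceptible nodes (`S`) become infected (`I`) and
recover (`R`) with rate μ.  Susceptibility is heterogeneous: node i in layer
α is infected per contact with probability β_i^α = ψ_i^α β + s, where β is
the baseline rate and s a contact-independent spontaneous-contagion
probability.  **Awareness** is an unaware–aware–faded process: unaware
nodes (`U`) become aware (`A`) through aware contacts with rate λ_i^α =
γ_i^α λ; aware nodes either *fade* (`F`, rate δ — they keep their awareness
but stop engaging) or, with rate ε, acquire *overlapping awareness*
(`A^π`) of secondary issues φ-correlated with the primary phenomenon.
Being aware is a precondition for infection: only aware susceptibles can be
infected, so awareness here is exposure-driving engagement with the
phenomenon, not protective knowledge.  The joint state space has 8
reachable states — SU, SA, SF, IA, IA^π, RA, RA^π, RF — and the
combinations IU, IF, SA^π, FA^π never occur.

The structural factors are γ = s_i^α/(1+s_i^α) (strength-saturating) and
ψ = 1/((1+λ_i^α) Y_i^α), where Y is the inverse participation ratio of the
node's weights; 1/Y is its effective contact count.  Note the direction
this implies: ψ ≥ 1/(1+λ) ≈ 1 for any node with more than one effective
contact, so structural heterogeneity *amplifies* hub susceptibility (see
Limitations).  Because β_i^α depends on λ_i^α, the awareness matrix Λ is
always built first and the infection matrix B second, in a single pass —
no fixed-point iteration between weights and rates is performed, since the
rate chain is defined once, not self-consistently.

Link weights are w_ij^α = h_ij · |awbar_i − awbar_j| + 1 with homophily
h_ij = 1/(1+δ_ij).  The attribute distance δ_ij defaults to |a_i − a_j| for
scalar attributes and to the discrete metric (0 same group / 1 otherwise)
for categorical ones, identical across layers; a per-layer attribute table
can be supplied but no experiment here uses one.  The overlapping awareness
awbar_i = aw_i (1 + Σ_π φ_{1,π}) is deliberately returned unclipped — it
may exceed 1 under reinforcing correlations or go negative under dominant
anti-correlations — and is floored at 0 before entering the weight
definition, since a negative engagement level has no meaning there.  It is
*not* renormalized to [0, 1]: rescaling would change the weight gaps that
encode the awareness differences.

## Probability recursion and step modes

The MMCA recursion updates each node's 8-state probability row through a
one-step branching tree, using

    q_i = (1 − β̄_i) Π_j [1 − a_ji p_j^I β̄_i]       (not infected)
    r_i = (1 − λ̄_i) Π_j [1 − a_ji p_j^A λ̄_j]       (stays unaware)

on the binary adjacency of the *elected* layer (the layer with maximal
influence score; an all-layers-union contact option exists behind a flag,
for both the solver and the stochastic simulator).  The asymmetry — q uses
the focal node's rate inside the product, r the neighbour's — is part of
the model definition and is implemented exactly; "fixing" it would change
the dynamics.  p^I counts IA and IA^π; p^A counts SA, IA and RA.

Two step modes exist.  `verbatim` applies the branching coefficients only;
iterated, it loses the mass of the absorbing states (SF, RA, RA^π, RF) and
of IA^π, because the one-step tree assigns them no self-persistence.
`conserving` (the default) adds exactly those terms — terminal states keep
their mass, IA^π persists with 1−μ and recovers into RA^π — after which
every row sums to 1 at every step (enforced at tolerance 1e-9).  All
results in the tests and the validation script use conserving mode;
verbatim mode is retained for fidelity experiments on the bare branching
equations.

The leading (1 − β̄_i) factor of q deserves its own paragraph.  Taken
literally it infects aware susceptibles at rate β̄_i even with zero
infected contacts — an unconditional spontaneous channel that makes ρ^I
scale as β p^SA/μ for *any* β > 0, so no threshold exists and phase
diagrams are structureless.  The threshold derivation itself linearizes q
around the infection-free state and keeps only the contact cross-term,
implicitly discarding this channel.  The package therefore exposes a
`leading` switch on the infection kernel: `"rate"` (the stated form, used
by `mmca_step`, the stochastic simulator and all solver-level validation)
and `"spontaneous"` (leading factor 1 − s, i.e. only the explicit
spontaneous-contagion probability), used by threshold detection and phase
diagrams, where a meaningful onset requires it.

## Stochastic simulator and exact enumeration

The agent simulator updates all nodes synchronously from the time-t
configuration with per-node branch probabilities *identical* to the MMCA
tree coefficients (verified to 1e-12 in the tests).  Awareness resolves
before infection within a step, but a node that becomes aware at step t is
infectable only from t+1 — the one-step tree routes SU mass only to
{SU, SA, SF}, and the simulator mirrors that exactly; allowing same-step
infection of the newly aware would systematically inflate incidence
relative to the recursion.  Replicates use RNG substreams keyed by
(master seed, run index), so ensembles are reproducible and a run's
trajectory does not depend on how many other runs were requested.  For
N ≤ ~6 the full joint chain (8^N states) can be evolved exactly; since the
synchronous kernel factorizes over nodes given the configuration, this
costs one product per configuration pair and turns the MMCA comparison
into a deterministic measurement of the independence-closure error alone.

## Threshold and onset detection

The analytic threshold is β_c = μ / Λ_max(H₀) with h⁰_ij = (1 − ε) ψ̄_i
p_i^SA a_ij, the baseline β factored out of β̄_i = ψ̄_i β.  p^SA is taken
from the awareness-only steady state (β = s = 0, δ = 0 — near the onset
fading is negligible by the derivation's own approximation).  The largest
real eigenvalue is computed densely below N = 300 and by sparse Arnoldi
iteration (with dense fallback) above.  An empty or fully suppressed
operator (ε → 1, or no links) yields β_c = +∞.

The *empirical* onset cannot use the stationary infected density: with
μ > 0 every trajectory ends with ρ^I = 0, because infection is transient
under recovery.  The order parameter with a genuine steady state is the
cumulative ever-infected mass.  Onset detection therefore starts from the
awareness steady state, seeds a uniform infected probability of 1e-5, runs
the conserving recursion with the spontaneous-leading kernel and δ = 0,
and declares an outbreak when the cumulative infected mass exceeds the
seed by 1e-3.  Below threshold the excess is O(seed/(1−R)); above it
O(R−1); with seed ≪ floor the detector flips within a fraction of a grid
step of the true onset (measured worst gap 0.009 against β_c on a 0.01
grid at ε = 0).  Outbreak occurrence is monotone in β, so grids are
scanned by bisection.  Phase grids additionally record the trajectory's
peak ρ^I per (λ, β) cell as the map quantity.

The stochastic threshold estimator uses the same philosophy: ensemble-mean
final attack fraction exceeding the seeded fraction by 5 points, on the
spontaneous-leading kernel.  On a finite stochastic system (N = 100) this
resolves the onset to about two grid steps; starting near the awareness
steady state (most nodes aware) removes the bias caused by seeds dying
before awareness saturates.

## Centrality and rewiring

The coupled ranking iterates, from uniform starts,

    X ← normalize(Σ_α z^α W^α X + c/N),    z^α ← normalize(X^T W^α X),

with damping c = 0.15 (guaranteeing irreducibility), tolerance 1e-10 and
at most 10⁴ iterations; both score vectors stay normalized to sum 1, and
all argmax/argmin ties break to the lowest index.  This realizes the
principle that nodes are central when active in influential layers and
layers influential when they connect central nodes; it is a self-contained
scheme, not a reimplementation of any published multiplex ranking variant.

Rewiring perturbs the layer with minimal z: the ⌊f·L⌋ links whose
lower-centrality endpoint has the smallest X are detached at that endpoint
and reattached to a uniformly random node, rejecting self-loops and
duplicates with up to 100 retries (the link is left in place afterwards),
preserving the layer's link count; weights are then recomputed from the
stored awareness assignment.  Rewiring is applied once per invocation —
callers wanting iterated rewiring with re-ranking loop explicitly.  Note a
structural consequence of electing a single contact layer: rewiring the
*least* central layer leaves the elected layer's adjacency — and hence the
elected-contact thresholds — unchanged except through shifts in the
ranking itself.

## Synthetic scenarios

The population generator emulates a communication-classified social-media
cohort: 7 class tiers with multinomial proportions (0.30, 0.22, 0.16,
0.12, 0.09, 0.07, 0.04) and a decreasing awareness gradient (0.90 → 0.15),
two groups (geographic-homophily proxy) with popularity factors (1.0,
0.85), and pre/post-event phases realised as awareness trend multipliers
(0.8 / 1.2) emulating the attention surge after a publicized event.  Node
awareness = clip(class level × group popularity × trend, 0, 1).  These
values are illustrative defaults, not calibrated to any corpus; the
lowest tiers are tagged "vulnerable".  Scale-free layers use seeded
Barabási–Albert preferential attachment (m = 2 unless stated), with
per-layer seeds spawned from the master seed.

Default rate parameters are λ = 0.2, β = 0.3, μ = 0.3, δ = 0.3, ε = 0.7,
s = 0 (all per-step probabilities); experiments use φ = ±0.8 for the
correlated issue and the three attention regimes (μ, δ, ε) ∈
{(0.3, 0.3, 0.7), (0.3, 0.7, 0.3), (0.7, 0.7, 0.3)}.  Validation problem
sizes: the one-step oracle and exact-chain comparisons run at N = 3 (100
randomized instances / 30 steps), conservation and ensemble agreement at
N = 200 (500 steps / 500 replicates), threshold bracketing at N = 100
over 10 network seeds, and the directional comparisons at N = 1000, M = 3
over 5 network seeds, matching the scale the synthetic scenarios target.

What the generator does *not* emulate: real degree correlations,
community structure, inter-layer degree correlations, temporal activity,
or any empirically calibrated awareness distribution.  Passing tests
demonstrate internal consistency of the solver, simulator and threshold
theory on these synthetic structures — not fidelity to any real
population.

## Known limitations

- **The analytic threshold neglects the overlapping-aware infectious
  state.**  H₀ tracks only IA near the onset, but IA^π is also infectious;
  including it multiplies the effective infection operator by
  (1 − εμ)/(1 − ε).  At ε = 0.7, μ = 0.3 the formula overestimates the
  dynamic onset by a factor ≈ 2.6; at ε = 0 it is exact.  Threshold
  self-consistency is therefore validated at ε = 0, and a unit test pins
  the bias direction (dynamic onset ≤ analytic β_c) for ε > 0.
- **Heterogeneity lowers the threshold.**  Since ψ ≈ k/(1+λ) ≥ 1 on
  non-leaf nodes, structure-derived rates make hubs more susceptible and
  the outbreak starts *earlier* than with uniform rates at the same
  baseline (measured median gap −0.03 at N = 1000).  A protective reading
  of heterogeneity would require the reciprocal factor ψ = Y/(1+λ); the
  implemented definition follows the model statement.
- **The φ-correlation's dynamic effect is weak.**  φ reaches the dynamics
  only through γ and ψ, whose shifts largely cancel; the anti- vs
  positively-correlated gap in time-averaged ρ^I is reproducibly ≤ 0 but
  of order 1e-8 at N = 1000, and mean infection rates over vulnerable
  nodes can order either way.  The per-node scatter of (λ_i, β_i, awbar_i)
  still separates the scenarios structurally.
- With β at its default 0.3, ψβ saturates the [0, 1] clip on about a
  quarter of node-layer pairs; rate-sensitive comparisons are better run
  at β ≲ 0.1.
- Directed or temporal multiplexes, inter-layer links, per-layer ε/μ/δ,
  time-varying φ, and continuous-time (Gillespie) dynamics are out of
  scope.
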
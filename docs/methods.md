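# Methods

## Overview

`netgames` simulates groups of *N* identical individuals that repeatedly
play a two-action game with neighbours on a fixed social network and learn
action preferences from the rewards they experience. The package's claim
is qualitative: negative frequency dependence plus individual
reinforcement learning produces behavioural specialization, faster and
more consistently when each individual has few network neighbours and when
learning is fast. Everything below documents the concrete model, the
defaults, and the choices made where the design was genuinely open.

## Networks

The baseline structure is a regular ring lattice: individual *i* is
connected to *i* ± 1, …, *i* ± *K*/2 (mod *N*), so every individual has
exactly *K* neighbours and the graph has *NK*/2 edges. *K* must be even,
except that *K* = *N* − 1 is allowed and yields the complete graph (the
all-connected case *K* = *N* − 1 = 98 for *N* = 99). Small-world variants
follow the Watts–Strogatz procedure: every lattice edge, visited in a
fixed canonical order (individuals 0…*N* − 1, each one's *K*/2 clockwise
edges), is independently rewired with probability *p*<sub>rew</sub> by
keeping the end at the visited individual and moving the far end to a
uniformly chosen non-neighbour. Edge count is conserved exactly; if no
legal target exists (near-complete graphs) the edge stays. Rewiring can
disconnect the graph; disconnected realizations are kept — isolated
individuals simply never interact (they earn nothing in the group games
and are never sampled for contests). Networks are immutable for the
lifetime of a group.

## Games

All rewards are in arbitrary "reward units"; probabilities are per round.

**Producer–scrounger.** Each round every individual chooses produce or
scrounge. A producer finds food with probability λ (`lambda_find`,
default 0.5 — a mid-range default, since no canonical value attaches to
the abstract game). On a find, up to n̂<sub>S</sub> (`max_scroungers`,
default 2) of its scrounging neighbours join, selected uniformly without
replacement; the producer eats a finder's advantage *V*₁ (default 1) and
the shareable amount *V*₂ (default 3) is split equally among producer and
joiners, so the producer earns *V*₁ + *V*₂/(*n*<sub>join</sub> + 1) and
each joiner *V*₂/(*n*<sub>join</sub> + 1). Every discovery distributes
exactly *V*₁ + *V*₂ in total. By default a scrounger may join several
neighbouring discoveries in the same round. This matters: if a scrounger
is instead capped at one discovery per round (`exclusive_joining=True`,
available for sensitivity analysis), a rare scrounger's income is capped
at a single share, scrounging never becomes lucrative when scroungers are
scarce, and the negative frequency dependence that drives specialization
largely disappears — with exclusivity, slow learners on a K = 4 lattice
never specialize at all. Multi-joining is therefore the default.

**Caller–satellite.** Each round every male calls or acts as satellite. A
caller's effective call strength is *s* = 1 − γ₀ *k*<sub>C</sub>/*k*,
where *k* is its neighbour count and *k*<sub>C</sub> how many neighbours
currently call (γ₀ default 0.75; an isolated caller has strength 1 — no
one interferes with it). The number of females arriving at the group is
Poisson with mean *f*·Σ*s* (f default 2); the Poisson choice is the
minimal stochastic model fixing only the mean, and a deterministic mode
(`deterministic_females=True`) pays expected rewards instead. Each female
approaches caller *j* with probability *s*<sub>*j*</sub>/Σ*s* and then
mates with exactly one male: the caller with certainty if it has no
satellite neighbours, otherwise the caller with probability 0.5 and each
of its *k*<sub>S</sub> satellite neighbours with probability
0.5/*k*<sub>S</sub>. A satellite adjacent to several callers can mate via
each of them — interception is local to the approached caller. Each
mating pays *V*₁ (default 2).

**Hawk–dove.** Contests are pairwise: a focal individual is drawn
uniformly among those with at least one neighbour, its opponent uniformly
among the focal's neighbours. Hawk against dove takes *V* (default 1);
two hawks escalate, a fair coin deciding who wins *V* and who pays the
cost *C* (default 2); two doves split by a fair coin (winner *V*, loser
0), which has the standard expected payoff *V*/2 each.

## Learning

**Action–value (Rescorla–Wagner).** Estimates *Q*<sub>A</sub>,
*Q*<sub>B</sub>; after performing an action with perceived reward *R*,
the chosen estimate moves by α(*R* − *Q*), the other is untouched. Choice
probability of A is the logistic of β(*Q*<sub>A</sub> − *Q*<sub>B</sub>).
Defaults α = 0.1 (fast; 0.01 for slow cases) and β = 8.

**Actor–critic.** A critic value *w* (expected reward of a round) and a
preference θ = logit *p*. With surprise δ = *R* − *w*: *w* ← *w* + αδ and
θ ← θ ± α<sub>pref</sub> δ (1 − *p*<sub>chosen</sub>), the sign following
the chosen action. The (1 − *p*<sub>chosen</sub>) factor is the
derivative of the log-policy, making this the canonical two-action
policy-gradient actor–critic; α<sub>pref</sub> defaults to α. θ is
clamped to ±12 (configurable) so logit(*p*) stays finite even under the
extreme preferences this rule develops at long times.

**Initial conditions.** Every individual starts at *p* = 0.5: both action
values (or the critic value, with θ = 0) start at a common `q_init`. By
default `q_init` is the expected one-round reward of the unbiased
starting population, computed in closed form per game
(producer–scrounger λ(*V*₁ + *V*₂)/2; caller–satellite
*f*(1 − γ₀/2)*V*₁/2; hawk–dove *V*/2 − *C*/8). This choice is load-bearing.
Starting the estimates at 0, far below the positive reward scale, acts as
*pessimistic* initialization: whichever action an individual happens to
sample first has its estimate pulled up while the other stays at the
origin, and with β = 8 this bootstrapping ratchet locks every individual
into an extreme preference within a couple of hundred rounds even at
α = 0.01. That makes slow learners polarize as fast as fast learners and
erases the regime in which slow learning in a fully connected group
averages long histories of nearly identical reward distributions and
stays weakly polarized — the model's key contrast. Initializing on the
reward scale removes the artefact of the arbitrary origin; `q_init` is
configurable for anyone who wants to study initialization effects
directly.

## Time accounting and the engine

For producer–scrounger and caller–satellite, all individuals commit their
actions simultaneously each round, the game resolves, and every
individual updates from its own reward (including zeros — the learner
sees the actual perceived reward every round). For hawk–dove, the group
experiences ⌊*NT*/2⌋ sequential contest events so that each individual
has an expected number *T* of contests; only the two contestants act and
update. For recording, one hawk–dove "round" is *N*/2 contest events,
which puts all three games on a common per-capita time grid so that
polarization trajectories and autocorrelation lags are comparable.
Whether several contests within such a round resolve simultaneously or
sequentially is not observable in the statistics we compute; sequential
resolution is used.

Reproducibility: every group *g* of an ensemble draws its RNG from
`SeedSequence([master_seed, g])`, so a group can be re-run bit-identically
in isolation and ensembles are order-independent. The RNG draw order
within a round is part of the engine's documented contract, which is what
makes the straight-line trace oracle in the test suite possible. Each
group draws its own network realization when *p*<sub>rew</sub> > 0.

## Metrics

**Polarization index.** *F* = Var(*p*)/(*p̄*(1 − *p̄*)) with *population*
(divide-by-*n*) variance — sample variance would push the two-individual
boundary case (0, 1) above 1, violating the index's range. When *p̄* is 0
or 1 the index is undefined and propagated as NaN, never silently zero;
group means skip undefined groups and report how many were skipped.

**Consistency.** For each lag ℓ, the product–moment correlation between
logit *p* at times *t* and *t* + ℓ, pooling every individual of every
group and every admissible start time inside an analysis window (default
4000–5000, i.e. a steady-state window of long runs). Pooling start times
trades a small loss of interpretability for a large gain in precision at
the bundled 5-group replicate counts. Probabilities are clamped to
[10⁻⁶, 1 − 10⁻⁶] before the logit. Zero pooled variance (all behaviour
identical) is flagged NaN.

## Bundled experiments and fixtures

The registry (`netgames.experiments.registry`) bundles the study designs:
producer–scrounger at *N* = 99 with *K* ∈ {4, 8, 98} × α ∈ {0.1, 0.01},
caller–satellite and hawk–dove with *K* ∈ {2, 8}, small-world variants at
*p*<sub>rew</sub> = 0.1, and long steady-state runs (*t* = 5000, 5 groups)
for the consistency analysis. Full designs use 500 replicate groups; each
case carries a reduced count (50, or the native 5 for consistency cases)
at which ensemble means are stable enough for the ordering comparisons
the test suite makes. The test suite and the bundled defaults use these
reduced sizes; they were chosen as the smallest ensembles at which the
qualitative contrasts are unambiguous across seeds.

`make_fixture` provides deterministic miniatures for tests: the
21-individual *K* = 4 ring, a 5-individual hand-traceable
producer–scrounger group, and synthetic trajectories whose logit(*p*)
follows a stationary AR(1) with chosen persistence ρ. The AR(1) fixture
is purely a measurement instrument for validating the autocorrelation
estimator against a known ground truth (lag-ℓ autocorrelation ρ^ℓ); it is
not a claim that the learning model produces AR(1) dynamics.

## What the simulations do and do not show

The model idealizes aggressively, by design: group members are identical
in learning and ability, payoff structures are stationary, networks are
fixed, and there is no state, no individual recognition, and no social
learning. Passing tests therefore demonstrate properties of the
idealized learning-in-games system — that network neighbourhood size and
learning rate shape specialization and consistency — not predictions
about any particular species. Real producer–scrounger systems involve
individual differences (sex, learning ability) that this model
deliberately omits.

Other known limitations: the caller–satellite female-arrival process is
only mean-constrained (Poisson chosen); λ for the producer–scrounger game
has no canonical value (0.5 chosen, configurable); the actor–critic rule
is the canonical policy-gradient form and other actor–critic variants
exist; and figure-level quantitative curves from any particular published
study are not targets — the package asserts orderings and exact boundary
identities, not read-off curve values.
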
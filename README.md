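# netgames

Agent-based simulation of reinforcement learning in two-action games with
negatively frequency-dependent payoffs, played on social networks.

## The problem

Members of animal groups often specialize: some forage for food while others
exploit their discoveries (producer–scrounger), some males call for mates
while others lurk to intercept (caller–satellite), some escalate contests
while others concede (hawk–dove). All three games share negative frequency
dependence — an action pays less the more of your interaction partners use
it — and individuals can *learn* which role to take from the rewards they
experience. `netgames` simulates groups of identical learners on a social
network and measures how the network (how many neighbours each individual
has) and the learning rate shape the emergence of behavioural
specialization and its consistency over time. It is aimed at behavioural
ecologists and game theorists studying learned specialization, animal
personality, and social-network effects on behaviour.

## Model

A group of *N* individuals sits on a regular ring lattice (each connected to
its *K*/2 nearest neighbours on either side) or on a Watts–Strogatz
small-world network derived from it by rewiring each edge with probability
*p*<sub>rew</sub>. Each round, individuals choose one of two actions and
receive rewards from one of three games (producer–scrounger,
caller–satellite, hawk–dove), resolved over the network neighbourhoods.

Two reinforcement-learning rules are implemented:

- **Action–value (Rescorla–Wagner) learning.** Each individual tracks
  estimates *Q*<sub>A</sub>, *Q*<sub>B</sub> of the reward of each action;
  after performing an action, *Q* ← *Q* + *α*(*R* − *Q*), and the
  probability of choosing A is the logistic of *β*(*Q*<sub>A</sub> −
  *Q*<sub>B</sub>), with sensitivity *β*.
- **Actor–critic learning.** A critic tracks the expected reward *w* of a
  round; an actor holds a preference *θ* = logit *p* updated in the
  direction of the chosen action by *α*<sub>pref</sub>·*δ*·(1 −
  *p*<sub>chosen</sub>), where *δ* = *R* − *w* is the critic's prediction
  error.

Two statistics summarize the outcome:

- **Polarization index** *F* = Var(*p*) / (*p̄*(1 − *p̄*)), the normalized
  (population) variance of the individual action probabilities, analogous
  to Wright's fixation index: *F* = 0 when everyone behaves alike, *F* = 1
  when the group splits into pure types.
- **Behavioural consistency**: the correlation of individual logit(*p*)
  between two time points, as a function of the time lag.

## Worked example

Ten replicate groups of N = 99 individuals on a K = 4 ring lattice playing
the producer–scrounger game with fast action–value learning (α = 0.1,
β = 8), versus the fully connected slow-learning case:

```python
import netgames as ng
from netgames.learning import LearnerParams

cfg = ng.SimulationConfig(
    n=99, k=4, game="producer_scrounger",
    learner=LearnerParams(alpha=0.1, beta=8.0),
    t_rounds=1000, n_groups=10, seed=42, record_interval=200,
)
trajs = ng.run_ensemble(cfg)
print(ng.polarization_series(trajs))

slow = ng.SimulationConfig(
    n=99, k=98, game="producer_scrounger",
    learner=LearnerParams(alpha=0.01, beta=8.0),
    t_rounds=1000, n_groups=10, seed=42, record_interval=200,
)
f_slow, _ = ng.mean_polarization([t.final_p for t in ng.run_ensemble(slow)])
print(f"K=98, alpha=0.01 at t=1000: mean F = {f_slow:.3f}")
```

prints

```
   round    mean_F  n_groups
0      0  0.000000        10
1    200  0.764886        10
2    400  0.776133        10
3    600  0.796615        10
4    800  0.794639        10
5   1000  0.808592        10
K=98, alpha=0.01 at t=1000: mean F = 0.144
```

With few neighbours and fast learning the groups polarize strongly into
producers and scroungers within a few hundred rounds (group-mean *F* ≈ 0.8);
with everyone connected and slow learning, value estimates average long
histories of nearly identical reward distributions and polarization stays
weak (*F* ≈ 0.14).

The same simulations are available from the shell:

```
netgames network --n 99 --k 4 --p-rew 0.1 --seed 42 --out net.tsv
netgames simulate --config sim.yaml --out results/
netgames metrics --traj results/trajectories.csv --out metrics/
netgames experiment --case fig2_K4_fast --groups 50 --seed 1 --out results/
```

(`netgames experiment --list --case x --out .` lists the bundled ensemble
designs.)

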
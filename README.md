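# agonistic

Quantitative genetics of runaway signal evolution driven by male–male
competition.

Elaborate weapons and displays that settle fights between males — antlers,
horns, forceps, badges of status — often seem to defy their ecological
optima. `agonistic` implements a quantitative-genetic model in which a
male **signal** (S) advertises **body size** (B, a proxy for fighting
ability) and modulates **aggression** (A) in dyadic contests. Because the
signal changes the behaviour of rivals, it is simultaneously a target and
a *source* of selection, and under simple, measurable conditions this
feedback produces self-accelerating (runaway) elaboration of signal and
body size together — an armament analogue of the Fisherian runaway from
female choice.

The package is for theoreticians exploring the dynamics and for
empiricists planning selection analyses of contest data: every model
quantity maps onto a regression an experimenter could run.

## The model

Signal and body size are ordinary metric traits, `z_i = a_i + e_i`, with
additive-genetic (co)variances `G_SS`, `G_BB`, `G_SB` (the **honesty**
covariance) and aggression genetically uncorrelated with both. Within a
dyad, aggression is socially contingent,

```
zA = aA + eA + δAS (zS − zS′),
```

(primes denote the opponent), and contest fitness follows a hawk–dove
payoff

```
w = w0 + bA (zA − zA′) − cA zA zA′ − cB zA′ zB′ − cS (z̄S − θS) zS ,
```

with benefit of out-escalating the rival `bA`, cost of mutual escalation
`cA`, threat of a large aggressive opponent `cB`, and natural selection
of strength `cS` pulling the signal toward its optimum `θS`. Partial
derivatives at the population mean give nonsocial gradients
`βNS = −cS(z̄S − θS)`, `βNB = 0`, `βNA = bA − cA z̄A` and social gradients
`βSS = 0`, `βSB = −cB z̄A`, `βSA = −(bA + cA z̄A + cB z̄B)`. The
per-generation response (selection on males only, hence the ½) is

```
Δz̄S = ½ G_SS [δAS(2bA + cB z̄B) − cS(z̄S − θS)]
Δz̄B = ½ G_SB [same bracket]
Δz̄A = ½ G_AA (bA − cA z̄A)
```

Aggression is self-limiting (`ẑA = bA/cA`), while signal and body size
share a line of equilibria `ẑS = θS + 2bA δAS/cS + (δAS cB/cS) ẑB` whose
slope is the evolutionary allometry of the signal. The line is unstable —
**runaway** — exactly when

```
(G_SB / G_SS) · δAS · cB  >  cS .
```

An individual-based contest simulator realizes the same model
stochastically, and an estimation layer recovers `δAS` and the cost and
benefit coefficients from simulated dyadic data by ordinary least
squares, exactly as a field study would.

## Worked example

With the reference coefficients (`bA = 0.2`, `cA = 0.05`, `cB = 0.2`,
`cS = 0.05`, `δAS = 0.4`, unit genetic variances) and weak honesty
(`G_SB = 0.4`):

```
$ agonistic simulate --config examples/stable.cfg --out out/stable
termination=converged classification=stable margin=-0.018
```

The equilibrium report (`out/stable/equilibrium.json`) reads

```json
{
  "zA_hat": 4.0,
  "line_intercept": 3.2,
  "line_slope": 1.6,
  "eigenvalues": [0.0, -0.009],
  "runaway": false,
  "margin": -0.018,
  "classification": "stable"
}
```

Mean aggression converges to `bA/cA = 4.0`; the population settles on
the line of equilibria `z̄S = 3.2 + 1.6 z̄B` (slope > 1: positive
allometry); the margin `(G_SB/G_SS) δAS cB − cS = 0.032 − 0.05 = −0.018`
and the negative Jacobian eigenvalue −0.009 both say the line attracts.
Raising honesty to `G_SB = 0.8` (`examples/runaway.cfg`) flips the margin
to +0.014 and the eigenvalue to +0.007:

```
$ agonistic simulate --config examples/runaway.cfg --out out/runaway
termination=diverged classification=runaway margin=0.014
```

Signal and body size now accelerate away together (locked to
`Δz̄B/Δz̄S = G_SB/G_SS = 0.8` each generation) while aggression still
plateaus at 4 — runaway driven purely by who fights whom, with no female
choice anywhere in the model.

The individual-based simulator and estimators close the empirical loop:

```python
import agonistic as ag

params = ag.ContestParams(deltaAS=0.4)
rngs = ag.spawn_rngs(1)
males = ag.sample_population(10_000, ag.PopulationState(),
                             ag.GeneticArchitecture(GSB=0.4), rngs["sampling"])
table = ag.run_contests(males, params, rng_pairing=rngs["pairing"],
                        rng_noise=rngs["noise"])
print(ag.estimate_deltaAS(table).estimates)   # {'deltaAS': 0.40125}
```

the regression slope of focal aggression on the signal difference
recovers the generating responsiveness 0.4 to sampling error.

## Layout

| module | contents |
| --- | --- |
| `agonistic.core` | parameter containers, aggression expression, contest fitness, analytic gradients |
| `agonistic.dynamics` | response equations and the generation iterator |
| `agonistic.equilibrium` | closed-form equilibria, runaway margin, Jacobian eigenvalues |
| `agonistic.simulate` | individual-based contest simulator (synthetic-data generator) |
| `agonistic.estimation` | OLS selection analysis, responsiveness regression, coefficient recovery |
| `agonistic.lande` | female-choice comparators (line of equilibria, runaway condition) |
| `agonistic.config`, `agonistic.cli` | key-value configs and the `agonistic` command |

See `docs/methods.md` for modelling assumptions, simulator design, and
known limitations.
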
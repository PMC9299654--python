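# Methods

## Model and assumptions

Three male traits: a signal `S`, the quality it advertises (body size
`B`), and aggression `A`. Signal and body size are classical polygenic
traits (`z = a + e`, breeding value plus independent non-heritable
deviation, both normal). Aggression is socially contingent: within a
dyad `zA = aA + eA + δAS (zS − zS′)`. The model's standing assumptions,
all fixed by construction in the code:

* breeding values and non-heritable deviations uncorrelated; both
  multivariate normal;
* no pleiotropy between aggression and the other traits (`G_SA = G_BA =
  0` are not representable as inputs); honesty enters only through
  `G_SB`;
* signal and body size are fixed before a contest and unchanged by it;
* pairwise duels between males drawn at random, one contest per male per
  generation;
* selection acts on males only; the genetic parameters and the fitness
  coefficients are constant through time (no G erosion, no drift in the
  deterministic layer).

Contest fitness is the quadratic hawk–dove payoff

`w = w0 + bA(zA − zA′) − cA zA zA′ − cB zA′ zB′ − cS(z̄S − θS) zS`.

This is a *local* model of relative fitness: the quadratic cost terms
eventually dominate far from the trait origin, which matters for the
individual-based layer (below).

## Deterministic dynamics

Discrete non-overlapping generations, additive updates
`z̄ ← z̄ + Δz̄` — no continuous-time approximation; the generation axis
of the trajectories is literal. The response equations contain the ½
multiplier for male-limited selection. The signal and body-size
responses share a single bracket, so the implementation computes the
bracket once; `Δz̄B · G_SS = Δz̄S · G_SB` then holds to float rounding
at every generation, and the per-generation ratio `Δz̄B/Δz̄S` equals
`G_SB/G_SS` wherever `Δz̄S ≠ 0`.

Iteration defaults: convergence when every |Δ| < 1e-10, divergence when
any |mean| > 1e6, cap of 10 000 generations. At the reference scales the
stable regime converges in ≈ 2 300 generations and the runaway regime
hits the bound in ≈ 1 600, so the classifications never collide. The
aggression recursion is linear with contraction factor `1 − ½ G_AA cA`
(0.975 at the reference values); it is stable whenever
`0 < ½ G_AA cA < 2` regardless of every other parameter.

## Equilibrium structure and stability

Closed forms: `ẑA = bA/cA` (requires `cA > 0`); the line of equilibria
`ẑS = θS + 2 bA δAS/cS + (δAS cB/cS) ẑB` (requires `cS > 0`). The
body-size-on-signal form of the line is derived by inverting the
signal-on-body form and cross-checked against its direct algebraic
expression `(cS/(δAS cB))(ẑS − θS) − 2bA/cB`.

Stability is assessed on the (S, B) subsystem only — the aggression
recursion is autonomous and contracting under the precondition above, so
it cannot destabilize anything. The 2×2 Jacobian of `(Δz̄S, Δz̄B)` has
rank one: one eigenvalue is always 0 (neutral motion along the line) and
the other equals `½(G_SB δAS cB − G_SS cS)`, whose sign matches the
runaway margin `(G_SB/G_SS) δAS cB − cS`. A margin within 1e-9 of zero
is reported as `"marginal"` rather than classified — the knife edge is
numerically meaningless.

## Individual-based simulator (the synthetic-data generator)

What it emulates: finite populations of duelling males at the exact
study conditions of the deterministic layer — trivariate-normal breeding
values with the honesty covariance, random perfect matching into dyads,
context-dependent aggression, hawk–dove fitness plus a mean-zero normal
deviate (variance `0.01 · w0²` by default), fitness-proportional sire
sampling, dams at the population mean. Defaults mirror the reference
parameterization: unit genetic variances and zero non-heritable
variances (the deterministic experiments specify genetic parameters
only; environmental variances are ordinary inputs when wanted, and none
of the closed forms depend on them).

Design choices:

* **Reproduction.** Sire counts are multinomial with probabilities
  proportional to relative fitness truncated at zero; each offspring's
  expected breeding value is ½ sire + ½ population mean, realizing the
  male-limited ½ with minimal machinery. The truncation count is stored
  in the table metadata.
* **Fitness normalization.** The table's fitness column is divided by
  its sample mean (standard selection-analysis practice). The division
  is refused if mean fitness is not positive, with a pointer to
  `calibrated_intercept`, which sets `w0` so that the closed-form
  expected fitness equals one. Multi-generation runs recalibrate the
  intercept every generation by default: only relative fitness matters
  for reproduction, and without recalibration the quadratic costs drive
  mean fitness negative once the means leave the origin.
* **Seeding.** One integer seed expands via `SeedSequence.spawn` into
  four named substreams — sampling, pairing, noise, reproduction — in
  that fixed order, so each component is independently reproducible and
  a fixed seed reproduces a contest table byte for byte.

What it does **not** emulate, hence what passing tests do not show about
real data: explicit loci, mutation, drift of the G matrix, overlapping
generations, repeated or non-random contests, female trait evolution,
and any fitness nonlinearity beyond the quadratic payoff.

Known bias: truncating negative fitness at zero weakens selection
against low-fitness males. At the reference conditions near the origin
about 2 % of males draw negative fitness and the one-generation signal
response is depressed by roughly 2 % — comparable to the 3-standard-error
band of the 20-replicate validation at n = 200 000, which is therefore a
deliberately tight check. The bias grows with distance from the origin
(the truncation count is reported for exactly this reason), which is why
long individual-based runaway trajectories elaborate more slowly than
the deterministic recursion even though the qualitative contrast between
regimes is preserved.

## Estimation layer

`estimate_gradients` is the standard multiple regression of relative
fitness on the six focal and opponent traits. It is consistent for the
analytic gradients because the predictors are jointly normal under the
generator; partial regression coefficients of a quadratic surface then
equal its average derivatives. This is a condition, not a theorem about
arbitrary data. Gradients are reported on natural trait scales;
variance-standardized output is a flag. A condition number above 1e6 on
the sd-scaled design aborts with the offending predictors named (the
practically relevant degeneracy: no intrinsic aggression variance makes
`zA` an exact combination of the two signals).

Because the fitness column was divided by its own sample mean, every
coefficient carries an extra relative uncertainty of `sd(w)/(√n · w̄)`
beyond the nominal OLS standard error, which conditions on the
normalization. `estimate_gradients` records this scale term and
`recover_costs` folds it into its delta-method standard errors; at the
shifted states used for cost recovery it is the dominant error term, and
ignoring it would understate the uncertainty of `ĉB` several-fold.

`estimate_deltaAS` regresses focal aggression on the signal difference;
the slope is unbiased for `δAS` only because aggression is assumed
genetically uncorrelated with the signal (with `G_SA ≠ 0` the regressor
would correlate with the residual; that regime is outside the model's
assumptions and is not handled).

`recover_costs` inverts the gradient expressions: `cB = −β̂SB/z̄A`,
`cS = −β̂NS/(z̄S − θS)`, and `(bA, cA)` from `β̂NA` at two states with
distinct mean aggression. Each inversion demands its denominator be
bounded away from zero; requesting an unidentifiable coefficient is an
error instructing a shifted-state design, and `targets` selects which
coefficients a given design supports.

## Problem sizes

The test suite and the acceptance script use: deterministic trajectories
up to 10 000 generations (coupling ratios read from 200-generation
runs); responsiveness recovery from tables of 10 000 males; gradient and
cost recovery from tables of 100 000 males; the one-generation
individual-based validation with 20 replicates of 200 000 males. At
these sizes the full suite runs in well under a minute and the
acceptance script in a few seconds.

## Limitations

* The payoff surface is local; conclusions far from the origin inherit
  the truncation bias discussed above.
* One contest per male per generation; multi-interaction tournaments
  would change the variance (not the mean) of selection.
* The female-choice comparators are static parameter maps for
  side-by-side classification; they do not simulate preference
  coevolution or linkage-disequilibrium buildup.
* Breeding-value means are the state variables of the individual-based
  layer; allele-frequency detail, and therefore any change in the G
  matrix, is out of scope.
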
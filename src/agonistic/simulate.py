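"""Individual-based Monte-Carlo realization of the contest model.

This is the package's synthetic-data generator.  Each generation it

1. samples ``n`` males, breeding values from the trivariate normal with
   the current means and genetic covariance matrix (honesty covariance
   GSB between signal and body size, aggression uncorrelated), plus
   independent non-heritable deviations;
2. pairs them into random duels (a perfect matching, one contest per
   male), expresses context-dependent aggression in each dyad, and
   assigns hawk-dove contest fitness plus a mean-zero normal deviate;
3. normalizes fitness to relative fitness and samples sires in
   proportion to it (negatives truncated to zero and counted); each
   offspring inherits half of its sire's breeding value and half of the
   population-mean breeding value, standing in for unselected dams.

The per-generation contest records double as synthetic observational
data for the estimation layer.

Randomness: one integer seed expands through ``numpy``'s SeedSequence
into four independent substreams, spawned in the fixed order
(sampling, pairing, noise, reproduction), so each component is
independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ContestParams,
    GeneticArchitecture,
    Male,
    PopulationState,
    calibrated_intercept,
)

logger = logging.getLogger("agonistic")

TABLE_COLUMNS = [
    "focal_zS",
    "focal_zB",
    "focal_zA",
    "opp_zS",
    "opp_zB",
    "opp_zA",
    "w",
]

#: variance of the fitness deviate, as a fraction of w0^2
NOISE_VARIANCE_FRACTION = 0.01


def spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Expand one seed into the four named substreams of a simulation run."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("sampling", "pairing", "noise", "reproduction")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class MalePopulation:
    """Array-backed collection of males (columns in trait order S, B, A)."""

    breeding: np.ndarray  # (n, 3) breeding values
    environment: np.ndarray  # (n, 3) non-heritable deviations

    def __len__(self) -> int:
        return self.breeding.shape[0]

    def __getitem__(self, i: int) -> Male:
        a, e = self.breeding[i], self.environment[i]
        return Male(aS=a[0], aB=a[1], aA=a[2], eS=e[0], eB=e[1], eA=e[2])

    @property
    def zS(self) -> np.ndarray:
        return self.breeding[:, 0] + self.environment[:, 0]

    @property
    def zB(self) -> np.ndarray:
        return self.breeding[:, 1] + self.environment[:, 1]

    @property
    def intrinsic_aggression(self) -> np.ndarray:
        return self.breeding[:, 2] + self.environment[:, 2]

    def mean_breeding(self) -> np.ndarray:
        return self.breeding.mean(axis=0)


@dataclass
class ContestTable:
    """One row per male: his traits, his opponent's traits, his fitness.

    Within every dyad each member contributes a row as focal and appears
    once as the other's opponent.  ``data`` is indexed by male; row ``i``
    of a freshly generated table corresponds to male ``i`` of the
    population it came from, which is what aligns fitness with breeding
    values during reproduction.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path, sidecar=None) -> None:
        self.data.to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(self.metadata, fh, indent=2, default=float)
                fh.write("\n")

    @classmethod
    def from_csv(cls, path, sidecar=None) -> "ContestTable":
        df = pd.read_csv(path)
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"contest table {path} is missing required column(s): "
                + ", ".join(missing)
            )
        meta: dict = {}
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
        return cls(data=df[TABLE_COLUMNS].copy(), metadata=meta)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD covariance matrix via its eigendecomposition."""
    vals, vecs = np.linalg.eigh(cov)
    if np.min(vals) < -1e-9 * max(1.0, np.max(np.abs(vals))):
        raise ValueError("covariance matrix is not positive semidefinite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def sample_population(
    n: int,
    state: PopulationState,
    G: GeneticArchitecture,
    seed: int | np.random.Generator = 0,
) -> MalePopulation:
    """Draw ``n`` males at the given population state.

    Breeding values come from the trivariate normal with means
    (meanS, meanB, meanA) and the genetic covariance matrix; deviations
    from the non-heritable covariance matrix with zero mean.  ``n`` must
    be even so that every male can be paired in a duel.
    """
    if n < 2 or n % 2:
        raise ValueError("population size must be even and at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Lg = _psd_factor(G.genetic_covariance())
    Le = _psd_factor(G.environmental_covariance())
    breeding = state.means() + rng.standard_normal((n, 3)) @ Lg.T
    environment = rng.standard_normal((n, 3)) @ Le.T
    return MalePopulation(breeding=breeding, environment=environment)


def run_contests(
    males: MalePopulation,
    params: ContestParams,
    seed: int | None = None,
    *,
    rng_pairing: np.random.Generator | None = None,
    rng_noise: np.random.Generator | None = None,
    noise_sd: float | None = None,
    normalize: bool = True,
) -> ContestTable:
    """Pair males into random duels and record traits and realized fitness.

    Pairing is a uniform random perfect matching; each male fights
    exactly one contest.  Fitness is the deterministic contest payoff
    plus an independent normal deviate (sd defaults to 0.1*|w0|) and is
    divided by its sample mean, giving relative fitness with sample mean
    exactly one.  The division fails if mean fitness is not positive,
    which happens when the quadratic cost terms dominate far from the
    trait origin - recalibrate the intercept first
    (:func:`agonistic.core.calibrated_intercept`).
    """
    n = len(males)
    if n % 2:
        raise ValueError("cannot pair an odd number of males")
    if rng_pairing is None or rng_noise is None:
        rngs = spawn_rngs(0 if seed is None else seed)
        rng_pairing = rng_pairing or rngs["pairing"]
        rng_noise = rng_noise or rngs["noise"]
    if noise_sd is None:
        noise_sd = np.sqrt(NOISE_VARIANCE_FRACTION) * abs(params.w0)

    perm = rng_pairing.permutation(n)
    partner = np.empty(n, dtype=int)
    partner[perm[: n // 2]] = perm[n // 2 :]
    partner[perm[n // 2 :]] = perm[: n // 2]

    zS, zB = males.zS, males.zB
    zA = males.intrinsic_aggression + params.deltaAS * (zS - zS[partner])
    zAp, zBp, zSp = zA[partner], zB[partner], zS[partner]
    mean_signal = zS.mean()

    w = (
        params.w0
        + params.bA * (zA - zAp)
        - params.cA * zA * zAp
        - params.cB * zAp * zBp
        - params.cS * (mean_signal - params.thetaS) * zS
    )
    if noise_sd > 0:
        w = w + rng_noise.normal(0.0, noise_sd, size=n)
    if normalize:
        wbar = w.mean()
        if wbar <= 0:
            raise ValueError(
                "sample mean fitness is not positive; the quadratic cost "
                "terms dominate at this state - regenerate with a larger "
                "intercept (see calibrated_intercept)"
            )
        w = w / wbar

    data = pd.DataFrame(
        {
            "focal_zS": zS,
            "focal_zB": zB,
            "focal_zA": zA,
            "opp_zS": zSp,
            "opp_zB": zBp,
            "opp_zA": zAp,
            "w": w,
        }
    )
    metadata = {
        "params": vars(params).copy(),
        "n": n,
        "seed": seed,
        "generation": None,
        "truncation_count": None,
        "normalized": normalize,
        "noise_sd": noise_sd,
    }
    return ContestTable(data=data, metadata=metadata)


def next_generation_means(
    table: ContestTable,
    males: MalePopulation,
    G: GeneticArchitecture,
    state: PopulationState,
    seed: int | np.random.Generator = 0,
) -> PopulationState:
    """Sample sires by fitness and return the offspring mean state.

    Sire counts are multinomial with probabilities proportional to
    relative fitness truncated at zero (the payoff surface is a local
    model; negative realized fitness means "does not reproduce").  The
    truncation count is recorded in ``table.metadata`` because the bias
    it introduces grows as the quadratic costs dominate far along a
    runaway.  Dams are unselected and carry the population-mean breeding
    value, so each offspring's expected breeding value is half sire,
    half population mean - the standard halving for selection acting on
    one sex.
    """
    n = len(males)
    if len(table) != n:
        raise ValueError("contest table and population sizes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = table.data["w"].to_numpy()
    w_pos = np.clip(w, 0.0, None)
    truncated = int((w < 0).sum())
    table.metadata["truncation_count"] = truncated
    total = w_pos.sum()
    if total <= 0:
        raise ValueError("all realized fitness is non-positive; selection is degenerate")
    counts = rng.multinomial(n, w_pos / total)
    mean_breeding = males.mean_breeding()
    offspring_mean = 0.5 * (counts @ males.breeding) / n + 0.5 * mean_breeding
    if truncated:
        logger.debug(
            "generation %d: truncated %d negative-fitness males (%.3f%%)",
            state.generation,
            truncated,
            100.0 * truncated / n,
        )
    return PopulationState(
        meanS=float(offspring_mean[0]),
        meanB=float(offspring_mean[1]),
        meanA=float(offspring_mean[2]),
        generation=state.generation + 1,
    )


def simulate_generations(
    initial: PopulationState,
    params: ContestParams,
    G: GeneticArchitecture,
    n: int,
    generations: int,
    seed: int = 0,
    keep_tables: bool = False,
    recalibrate_intercept: bool = True,
) -> tuple[list[PopulationState], list[ContestTable]]:
    """Run the individual-based model forward for several generations.

    Returns the per-generation mean states (length ``generations + 1``)
    and, if ``keep_tables``, the contest table of every generation.

    By default the fitness intercept is recalibrated every generation so
    that expected fitness stays at one (see
    :func:`agonistic.core.calibrated_intercept`).  Only relative fitness
    matters for reproduction, and without recalibration the quadratic
    cost terms drive mean fitness negative once the trait means leave
    the neighbourhood of the origin, at which point fitness-proportional
    reproduction is undefined.
    """
    rngs = spawn_rngs(seed)
    state = initial
    states = [state]
    tables: list[ContestTable] = []
    for g in range(generations):
        p_gen = params
        if recalibrate_intercept:
            p_gen = params.with_intercept(calibrated_intercept(params, G, state))
        males = sample_population(n, state, G, rngs["sampling"])
        table = run_contests(
            males,
            p_gen,
            rng_pairing=rngs["pairing"],
            rng_noise=rngs["noise"],
        )
        table.metadata["generation"] = state.generation
        table.metadata["seed"] = seed
        state = next_generation_means(table, males, G, state, rngs["reproduction"])
        states.append(state)
        if keep_tables:
            tables.append(table)
    return states, tables
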
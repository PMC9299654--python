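"""Core model of socially contingent aggression and contest fitness.

Three male traits are modelled: a signal of fighting ability (S), body
size (B, the quality the signal advertises), and aggression (A).  Signal
and body size are ordinary quantitative traits, ``z_i = a_i + e_i``, with
breeding value ``a_i`` and non-heritable deviation ``e_i``.  Aggression is
socially contingent: within a dyadic contest a male expresses

    zA = aA + eA + deltaAS * (zS - zS'),

escalating against rivals whose signal is smaller than his own and
de-escalating against larger-signalled rivals (primed symbols denote the
opponent).  Fitness in a duel follows a hawk-dove-derived payoff

    w = w0 + bA*(zA - zA') - cA*zA*zA' - cB*zA'*zB' - cS*(zbarS - thetaS)*zS,

combining the benefit of out-escalating the rival (bA), the cost of
mutual escalation (cA), the threat posed by a large aggressive opponent
(cB), and natural selection pulling the signal toward its optimum
thetaS (cS).  Partial derivatives of this surface at the population mean
give the nonsocial (focal-trait) and social (opponent-trait) selection
gradients used by the evolutionary dynamics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("agonistic")

#: numerical slack used when validating covariance bounds
_PSD_TOL = 1e-9

TRAITS = ("S", "B", "A")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticArchitecture:
    """Additive-genetic and non-heritable (co)variances of the three traits.

    The genetic covariance between the signal and body size, ``GSB``,
    quantifies signal honesty.  Aggression is assumed genetically
    uncorrelated with both other traits (no pleiotropy), so those
    covariances are fixed at zero by construction and are not fields.

    Defaults are the parameterization used throughout the worked
    examples: unit genetic variance for every trait, honesty covariance
    0.4, and no non-heritable variance (the deterministic experiments
    specify genetic parameters only; set ``ESS`` etc. for less heritable
    traits).
    """

    GSS: float = 1.0
    GBB: float = 1.0
    GAA: float = 1.0
    GSB: float = 0.4
    ESS: float = 0.0
    EBB: float = 0.0
    EAA: float = 0.0
    ESB: float = 0.0

    def __post_init__(self) -> None:
        for name in ("GSS", "GBB", "GAA", "ESS", "EBB", "EAA"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance {name} must be non-negative")
        if abs(self.GSB) > np.sqrt(self.GSS * self.GBB) + _PSD_TOL:
            raise ValueError(
                "genetic covariance GSB exceeds sqrt(GSS*GBB); "
                "the genetic covariance matrix is not positive semidefinite"
            )
        if abs(self.ESB) > np.sqrt(self.ESS * self.EBB) + _PSD_TOL:
            raise ValueError(
                "non-heritable covariance ESB exceeds sqrt(ESS*EBB)"
            )

    def genetic_covariance(self) -> np.ndarray:
        """3x3 additive-genetic covariance matrix in trait order (S, B, A)."""
        return np.array(
            [
                [self.GSS, self.GSB, 0.0],
                [self.GSB, self.GBB, 0.0],
                [0.0, 0.0, self.GAA],
            ]
        )

    def environmental_covariance(self) -> np.ndarray:
        """3x3 non-heritable covariance matrix in trait order (S, B, A)."""
        return np.array(
            [
                [self.ESS, self.ESB, 0.0],
                [self.ESB, self.EBB, 0.0],
                [0.0, 0.0, self.EAA],
            ]
        )

    def phenotypic_covariance(self) -> np.ndarray:
        return self.genetic_covariance() + self.environmental_covariance()


@dataclass(frozen=True)
class ContestParams:
    """Coefficients of the contest fitness surface and the aggression rule.

    bA
        Fitness benefit of out-escalating the opponent (per unit of the
        aggression difference).
    cA
        Cost of mutual escalation (hawk-vs-hawk injuries).
    cB
        Threat of the opponent: cost imposed by opponent aggression per
        unit of opponent body size.
    cS
        Strength of natural (viability) selection pulling the signal
        toward its optimum.
    thetaS
        Naturally selected signal optimum.
    deltaAS
        Responsiveness of aggression to the focal-minus-opponent signal
        difference; the interacting-phenotypes psi of this model.
    w0
        Relative-fitness intercept.  The dynamics are invariant to it;
        the individual-based simulator needs it large enough that
        realized fitness is rarely negative (see
        :func:`calibrated_intercept`).

    Defaults are the canonical stable-regime parameterization of the
    worked examples.
    """

    bA: float = 0.2
    cA: float = 0.05
    cB: float = 0.2
    cS: float = 0.05
    thetaS: float = 0.0
    deltaAS: float = 0.4
    w0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bA", "cA", "cB", "cS"):
            if getattr(self, name) < 0:
                raise ValueError(f"coefficient {name} must be non-negative")

    def with_intercept(self, w0: float) -> "ContestParams":
        return dataclasses.replace(self, w0=w0)


@dataclass(frozen=True)
class PopulationState:
    """Population mean trait values at a given generation.

    ``meanA`` is the mean *intrinsic* aggression (mean breeding value
    plus mean non-heritable deviation).  Because opponents are drawn at
    random, the socially contingent deltaAS term averages to zero, so
    this also equals the mean expressed aggression.
    """

    meanS: float = 0.0
    meanB: float = 0.0
    meanA: float = 0.0
    generation: int = 0

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    def means(self) -> np.ndarray:
        return np.array([self.meanS, self.meanB, self.meanA])

    def step(self, delta: np.ndarray) -> "PopulationState":
        """State after adding a per-generation response vector."""
        return PopulationState(
            meanS=self.meanS + float(delta[0]),
            meanB=self.meanB + float(delta[1]),
            meanA=self.meanA + float(delta[2]),
            generation=self.generation + 1,
        )


@dataclass(frozen=True)
class SelectionGradients:
    """Nonsocial (betaN*) and social (betaS*) directional selection gradients.

    Nonsocial gradients are partial regressions of focal relative fitness
    on the focal male's own traits; social gradients on his opponent's
    traits.  Under the contest fitness surface ``betaNB`` and ``betaSS``
    are identically zero: body size only harms *others* (through the
    threat term) and a rival's signal only acts by modulating behaviour,
    not fitness directly.
    """

    betaNS: float
    betaNB: float
    betaNA: float
    betaSS: float
    betaSB: float
    betaSA: float

    @property
    def betaN(self) -> np.ndarray:
        return np.array([self.betaNS, self.betaNB, self.betaNA])

    @property
    def betaS(self) -> np.ndarray:
        return np.array([self.betaSS, self.betaSB, self.betaSA])


@dataclass
class Male:
    """A single male: breeding values, non-heritable deviations, phenotypes.

    ``zS`` and ``zB`` are fixed at birth and never altered by a contest;
    ``zA`` is context dependent and only set once the male is placed in a
    dyad (see :func:`express_aggression`).
    """

    aS: float = 0.0
    aB: float = 0.0
    aA: float = 0.0
    eS: float = 0.0
    eB: float = 0.0
    eA: float = 0.0
    zA: float | None = field(default=None, compare=False)

    @property
    def zS(self) -> float:
        return self.aS + self.eS

    @property
    def zB(self) -> float:
        return self.aB + self.eB

    @property
    def intrinsic_aggression(self) -> float:
        return self.aA + self.eA


# ---------------------------------------------------------------------------
# model equations
# ---------------------------------------------------------------------------

def express_aggression(focal: Male, opponent: Male, params: ContestParams) -> float:
    """Aggression phenotype of ``focal`` when facing ``opponent``.

    zA = aA + eA + deltaAS*(zS - zS').  The deltaAS contributions of the
    two members of a dyad are equal in magnitude and opposite in sign.
    """
    return focal.aA + focal.eA + params.deltaAS * (focal.zS - opponent.zS)


def contest_fitness(
    focal: Male,
    opponent: Male,
    params: ContestParams,
    mean_signal: float,
) -> float:
    """Deterministic relative fitness of ``focal`` in a duel.

    Both males must already have expressed aggression within this dyad.
    ``mean_signal`` is the current population mean of the signal; natural
    selection against the signal strengthens as the population mean moves
    away from the optimum.  The stochastic deviate of realized fitness
    lives in the individual-based simulator, not here.
    """
    if focal.zA is None or opponent.zA is None:
        raise ValueError(
            "aggression not expressed; call express_aggression for both "
            "members of the dyad first"
        )
    return (
        params.w0
        + params.bA * (focal.zA - opponent.zA)
        - params.cA * focal.zA * opponent.zA
        - params.cB * opponent.zA * opponent.zB
        - params.cS * (mean_signal - params.thetaS) * focal.zS
    )


def analytic_gradients(params: ContestParams, state: PopulationState) -> SelectionGradients:
    """Selection gradients implied by the contest fitness surface.

    Partial derivatives of dyadic fitness with respect to focal and
    opponent traits, evaluated at the population mean:

        betaNS = -cS*(zbarS - thetaS)      betaSS = 0
        betaNB = 0                         betaSB = -cB*zbarA
        betaNA = bA - cA*zbarA             betaSA = -(bA + cA*zbarA + cB*zbarB)
    """
    return SelectionGradients(
        betaNS=-params.cS * (state.meanS - params.thetaS),
        betaNB=0.0,
        betaNA=params.bA - params.cA * state.meanA,
        betaSS=0.0,
        betaSB=-params.cB * state.meanA,
        betaSA=-(params.bA + params.cA * state.meanA + params.cB * state.meanB),
    )


def mean_fitness(
    params: ContestParams,
    G: GeneticArchitecture,
    state: PopulationState,
) -> float:
    """Expected contest fitness over random dyads at a population state.

    Closed form of E[w] under the generative model.  The benefit term
    vanishes (it is zero-sum within a dyad) but the two product costs do
    not reduce to products of means: random pairing plus the socially
    contingent aggression rule induces a negative covariance between the
    dyad members' aggression, Cov(zA, zA') = -2*deltaAS^2*PSS, and an
    honesty-driven one between a male's aggression and his own body
    size, Cov(zA, zB) = deltaAS*PSB (P = phenotypic (co)variance).
    """
    PSS = G.GSS + G.ESS
    PSB = G.GSB + G.ESB
    e_zA_zAp = state.meanA**2 - 2.0 * params.deltaAS**2 * PSS
    e_zAp_zBp = state.meanA * state.meanB + params.deltaAS * PSB
    return (
        params.w0
        - params.cA * e_zA_zAp
        - params.cB * e_zAp_zBp
        - params.cS * (state.meanS - params.thetaS) * state.meanS
    )


def calibrated_intercept(
    params: ContestParams,
    G: GeneticArchitecture,
    state: PopulationState,
) -> float:
    """Intercept w0 that makes expected contest fitness equal one.

    The fitness surface is a local (second-order) model and its intercept
    carries no biological content; on the relative-fitness scale the
    population mean should be one.  Use this before generating contest
    tables at states far from the origin, where the quadratic cost terms
    would otherwise drive mean fitness negative.
    """
    return 1.0 - (mean_fitness(params, G, state) - params.w0)
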
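"""Equilibria, stability, and the runaway classification.

Setting the mean-trait recursion to zero gives a point equilibrium for
aggression, ``zA_hat = bA/cA``, and a one-dimensional *line* of
equilibria in the (signal, body size) plane,

    zS_hat = thetaS + 2*bA*deltaAS/cS + (deltaAS*cB/cS) * zB_hat.

The slope deltaAS*cB/cS is the evolutionary allometry of the signal:
populations compared through time or across space should fall on this
line when it is stable.  Stability hinges on whether honesty-coupled
body-size evolution outpaces natural selection on the signal:

    runaway  <=>  (GSB/GSS) * deltaAS * cB > cS.

Equivalently, the Jacobian of the (signal, body) update map has
eigenvalues {0, (GSB*deltaAS*cB - GSS*cS)/2}; the zero eigenvalue is the
direction along the line, and a positive second eigenvalue makes the
line repelling (runaway).  Aggression is excluded from the Jacobian
because its recursion is autonomous and contracting whenever
0 < GAA*cA/2 < 2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np

from .core import ContestParams, GeneticArchitecture

logger = logging.getLogger("agonistic")

#: |margin| below which the knife-edge case is reported as "marginal"
MARGIN_DEAD_BAND = 1e-9


def aggression_equilibrium(params: ContestParams) -> float:
    """Equilibrium mean aggression, bA/cA (requires a cost of escalation)."""
    if params.cA <= 0:
        raise ValueError(
            "cA must be positive: without a cost of mutual escalation "
            "aggression has no finite equilibrium"
        )
    return params.bA / params.cA


def equilibrium_line(params: ContestParams) -> tuple[float, float]:
    """(intercept, slope) of mean signal as a function of mean body size.

    intercept = thetaS + 2*bA*deltaAS/cS, slope = deltaAS*cB/cS.  The
    slope is the evolutionary allometry of the signal; slope > 1 means
    positive allometry.
    """
    if params.cS <= 0:
        raise ValueError(
            "cS must be positive: without natural selection on the signal "
            "the line of equilibria is undefined (pure runaway whenever "
            "deltaAS*cB > 0)"
        )
    intercept = params.thetaS + 2.0 * params.bA * params.deltaAS / params.cS
    slope = params.deltaAS * params.cB / params.cS
    return intercept, slope


def body_size_line(params: ContestParams) -> tuple[float, float]:
    """(intercept, slope) of mean body size as a function of mean signal.

    The same line of equilibria solved the other way around; derived by
    inverting :func:`equilibrium_line`, which requires deltaAS*cB > 0.
    Algebraically: zB_hat = (cS/(deltaAS*cB))*(zS_hat - thetaS) - 2*bA/cB.
    """
    intercept_s, slope_s = equilibrium_line(params)
    if slope_s == 0:
        raise ValueError(
            "line of equilibria is horizontal (deltaAS*cB = 0); body size "
            "cannot be expressed as a function of signal"
        )
    return -intercept_s / slope_s, 1.0 / slope_s


def runaway_condition(
    params: ContestParams, G: GeneticArchitecture
) -> tuple[bool, float]:
    """Strict runaway test and its margin.

    margin = (GSB/GSS)*deltaAS*cB - cS; runaway iff margin > 0.  A
    positive margin means the indirect, honesty-mediated force of social
    selection on the signal exceeds natural selection against it, so the
    line of equilibria repels and signal and body size elaborate without
    bound (or collapse, on the other side of the line).
    """
    if G.GSS <= 0:
        raise ValueError("GSS must be positive to evaluate the runaway condition")
    margin = (G.GSB / G.GSS) * params.deltaAS * params.cB - params.cS
    return margin > 0, margin


def jacobian_matrix(params: ContestParams, G: GeneticArchitecture) -> np.ndarray:
    """Jacobian of the (signal, body size) per-generation update map.

    Partial derivatives of (dS, dB) with respect to (meanS, meanB); the
    aggression subsystem is autonomous and excluded.
    """
    return 0.5 * np.array(
        [
            [-G.GSS * params.cS, G.GSS * params.deltaAS * params.cB],
            [-G.GSB * params.cS, G.GSB * params.deltaAS * params.cB],
        ]
    )


def jacobian_eigenvalues(
    params: ContestParams, G: GeneticArchitecture
) -> tuple[float, float]:
    """Eigenvalues of the (S, B) Jacobian, ordered (zero, nonzero).

    The matrix has rank one, so one eigenvalue is always zero (motion
    along the line of equilibria is neutral) and the other equals the
    trace, (GSB*deltaAS*cB - GSS*cS)/2.  Its sign agrees with the
    runaway margin.
    """
    eig = np.linalg.eigvals(jacobian_matrix(params, G))
    eig = np.real_if_close(eig, tol=1e3)
    order = np.argsort(np.abs(eig))
    return float(np.real(eig[order[0]])), float(np.real(eig[order[1]]))


@dataclass(frozen=True)
class EquilibriumReport:
    """Closed-form equilibrium structure and stability classification."""

    zA_hat: float
    line_intercept: float
    line_slope: float
    eigenvalues: tuple[float, float]
    runaway: bool
    margin: float
    #: "stable", "runaway", or "marginal" (|margin| inside the dead band)
    classification: str = "stable"
    mechanism: str = "male_competition"

    def to_json(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        doc["eigenvalues"] = list(self.eigenvalues)
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def analyze(params: ContestParams, G: GeneticArchitecture) -> EquilibriumReport:
    """Full equilibrium/stability report for one parameterization."""
    runaway, margin = runaway_condition(params, G)
    intercept, slope = equilibrium_line(params)
    eig = jacobian_eigenvalues(params, G)
    if abs(margin) < MARGIN_DEAD_BAND:
        classification = "marginal"
    else:
        classification = "runaway" if runaway else "stable"
    report = EquilibriumReport(
        zA_hat=aggression_equilibrium(params),
        line_intercept=intercept,
        line_slope=slope,
        eigenvalues=eig,
        runaway=runaway,
        margin=margin,
        classification=classification,
    )
    logger.info(
        "equilibrium: %s (margin %.6g, nonzero eigenvalue %.6g)",
        classification,
        margin,
        eig[1],
    )
    return report
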
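"""Static comparators for runaway driven by female mate choice.

In the classic female-choice model (relative preferences), the male
trait mean z and female preference mean y settle on a line of equilibria

    z_hat = theta + (bSS/cNS) * y_hat,

which is unstable - runaway - when (Gmf/Gmm)*bSS > cNS, with Gmf the
trait-preference genetic covariance built up by assortative mating.

The male-contest model maps onto this structure exactly under

    Gmf  <-> GSB (signal honesty, via pleiotropy rather than linkage
              disequilibrium),
    Gmm  <-> GSS,
    bSS  <-> deltaAS * cB (social selection routed through behavioural
              responsiveness),
    cNS  <-> cS.

These comparators exist to make that parallel checkable side by side;
they deliberately carry no preference-evolution dynamics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

logger = logging.getLogger("agonistic")


@dataclass(frozen=True)
class LandeParams:
    """Parameters of the female-choice line of equilibria and runaway test.

    theta: naturally selected optimum of the male trait.
    bSS: strength of sexual selection from female preference.
    cNS: strength of natural selection on the male trait.
    Gmm: genetic variance of the male trait.
    Gmf: genetic covariance between male trait and female preference.
    """

    theta: float
    bSS: float
    cNS: float
    Gmm: float
    Gmf: float

    def __post_init__(self) -> None:
        if self.Gmm <= 0:
            raise ValueError("male-trait genetic variance Gmm must be positive")


def lande_line(p: LandeParams) -> tuple[float, float]:
    """(intercept, slope) of the male-trait mean on the preference mean."""
    if p.cNS <= 0:
        raise ValueError(
            "cNS must be positive: without natural selection the "
            "female-choice line of equilibria is undefined"
        )
    return p.theta, p.bSS / p.cNS


def lande_runaway(p: LandeParams) -> tuple[bool, float]:
    """Strict female-choice runaway test and its margin.

    margin = (Gmf/Gmm)*bSS - cNS; runaway iff margin > 0.
    """
    margin = (p.Gmf / p.Gmm) * p.bSS - p.cNS
    return margin > 0, margin


def report(p: LandeParams, path=None) -> dict:
    """JSON-ready stability report, same shape as the contest-model one."""
    runaway, margin = lande_runaway(p)
    intercept, slope = lande_line(p)
    doc = {
        "line_intercept": intercept,
        "line_slope": slope,
        "runaway": runaway,
        "margin": margin,
        "classification": "runaway" if runaway else "stable",
        "mechanism": "female_choice",
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    return doc
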
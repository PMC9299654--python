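"""Recovering model quantities from dyadic contest data, empiricist-style.

Two regressions an experimenter could run on observed duels:

* the Lande-Arnold-style selection analysis - multiple regression of
  focal relative fitness on the focal male's traits (nonsocial
  gradients) and his opponent's traits (social gradients);
* the responsiveness regression - focal aggression on the
  focal-minus-opponent signal difference, whose slope is deltaAS.

The gradient regression is unbiased for the analytic gradients because
the six predictors are jointly normal under the generative model, in
which case partial regression coefficients of a (quadratic) fitness
surface equal its average derivatives.  :func:`recover_costs` then
inverts the analytic gradient expressions to return the underlying cost
and benefit coefficients.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import PopulationState
from .simulate import ContestTable

logger = logging.getLogger("agonistic")

MIN_ROWS = 50
CONDITION_NUMBER_LIMIT = 1e6

GRADIENT_NAMES = ("betaNS", "betaNB", "betaNA", "betaSS", "betaSB", "betaSA")
PREDICTORS = ("focal_zS", "focal_zB", "focal_zA", "opp_zS", "opp_zB", "opp_zA")


@dataclass
class EstimationResult:
    """Coefficient estimates with standard errors plus fit diagnostics."""

    kind: str
    estimates: dict[str, float]
    se: dict[str, float]
    n: int
    r_squared: float
    condition_number: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, est in self.estimates.items():
            if not np.isfinite(est):
                raise ValueError(f"estimate {name} is not finite")
            if not (np.isfinite(self.se[name]) and self.se[name] > 0):
                raise ValueError(f"standard error of {name} must be finite and positive")

    def to_json(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _check_table(table: ContestTable) -> None:
    if len(table) < MIN_ROWS:
        raise ValueError(
            f"need at least {MIN_ROWS} contest rows, got {len(table)}"
        )


def _check_collinearity(X: np.ndarray, names: tuple[str, ...]) -> float:
    """Condition number of the sd-scaled design; raises naming the culprits."""
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = [n for n, s in zip(names, sd) if s == 0]
        raise ValueError("predictor(s) with zero variance: " + ", ".join(dead))
    Xs = (X - X.mean(axis=0)) / sd
    _, sing, vt = np.linalg.svd(Xs, full_matrices=False)
    cond = sing[0] / sing[-1] if sing[-1] > 0 else np.inf
    if cond > CONDITION_NUMBER_LIMIT:
        weights = np.abs(vt[-1])
        involved = [n for n, wgt in zip(names, weights) if wgt > 0.3]
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}): "
            + ", ".join(involved or names)
        )
    return float(cond)


def estimate_gradients(
    table: ContestTable, standardize: bool = False
) -> EstimationResult:
    """Selection-analysis regression on a contest table.

    Ordinary least squares of relative fitness on the six focal and
    opponent traits with an intercept.  With ``standardize`` the
    gradients are multiplied by the predictor standard deviations
    (variance-standardized gradients); the default keeps natural trait
    scales.  The intercept is reported in ``extra`` but carries no
    interpretation.
    """
    _check_table(table)
    X = table.data[list(PREDICTORS)].to_numpy()
    y = table.data["w"].to_numpy()
    cond = _check_collinearity(X, PREDICTORS)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    scale = X.std(axis=0, ddof=1) if standardize else np.ones(X.shape[1])
    estimates = {
        name: float(fit.params[i + 1] * scale[i])
        for i, name in enumerate(GRADIENT_NAMES)
    }
    se = {
        name: float(fit.bse[i + 1] * scale[i])
        for i, name in enumerate(GRADIENT_NAMES)
    }
    return EstimationResult(
        kind="selection_gradients",
        estimates=estimates,
        se=se,
        n=len(table),
        r_squared=float(fit.rsquared),
        condition_number=cond,
        extra={
            "intercept": float(fit.params[0]),
            "standardized": standardize,
            # relative sampling uncertainty of the within-sample mean-fitness
            # normalization; propagate when converting gradients to model
            # coefficients (the OLS SEs condition on the normalization).
            "fitness_scale_rel_se": float(
                y.std(ddof=1) / (np.sqrt(len(y)) * abs(y.mean()))
            ),
        },
    )


def estimate_deltaAS(table: ContestTable) -> EstimationResult:
    """Responsiveness regression: focal aggression on the signal difference.

    The slope estimates deltaAS, unbiased under the model's assumption
    that the breeding value of aggression is uncorrelated with the
    signal (no pleiotropy); the signal difference is then independent of
    the residual intrinsic aggression.
    """
    _check_table(table)
    x = (table.data["focal_zS"] - table.data["opp_zS"]).to_numpy()
    y = table.data["focal_zA"].to_numpy()
    if x.var(ddof=1) <= 1e-12:
        raise ValueError(
            "signal difference has (near-)zero variance; deltaAS is not identifiable"
        )
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return EstimationResult(
        kind="responsiveness",
        estimates={"deltaAS": float(fit.params[1])},
        se={"deltaAS": float(fit.bse[1])},
        n=len(table),
        r_squared=float(fit.rsquared),
        condition_number=1.0,
        extra={"intercept": float(fit.params[0])},
    )


def _ratio_se(est: float, se: float, rel_scale_se: float) -> float:
    """Delta-method SE of a gradient-derived ratio, including the extra
    relative uncertainty from the within-sample fitness normalization."""
    return float(np.sqrt(se**2 + (est * rel_scale_se) ** 2))


def recover_costs(
    gradients: EstimationResult,
    state: PopulationState,
    thetaS: float = 0.0,
    second: tuple[EstimationResult, PopulationState] | None = None,
    targets: tuple[str, ...] | None = None,
) -> EstimationResult:
    """Invert estimated gradients into contest coefficients.

    * cB = -betaSB / meanA (needs meanA away from zero);
    * cS = -betaNS / (meanS - thetaS) (needs the signal mean displaced
      from its optimum);
    * bA and cA need betaNA measured at two states with distinct mean
      aggression, solving bA - cA*meanA = betaNA as a 2x2 linear system.

    ``targets`` selects which coefficients to recover (default: cB and
    cS, plus bA and cA when a second state is supplied); requesting a
    coefficient that is unidentifiable at the given state is an error
    instructing a shifted-state design.

    Standard errors are delta-method propagations of the gradient SEs
    (treated as independent between the two states), inflated by the
    relative-fitness normalization uncertainty recorded by
    :func:`estimate_gradients`.
    """
    eps = 1e-8
    if targets is None:
        targets = ("cB", "cS") + (("bA", "cA") if second is not None else ())
    rel = gradients.extra.get("fitness_scale_rel_se", 0.0)
    estimates: dict[str, float] = {}
    se: dict[str, float] = {}

    if "cB" in targets:
        if abs(state.meanA) <= eps:
            raise ValueError(
                "mean aggression is (near) zero: cB is unidentifiable; use a "
                "shifted-state design with nonzero mean aggression"
            )
        estimates["cB"] = -gradients.estimates["betaSB"] / state.meanA
        se["cB"] = _ratio_se(
            estimates["cB"], gradients.se["betaSB"] / abs(state.meanA), rel
        )

    if "cS" in targets:
        displacement = state.meanS - thetaS
        if abs(displacement) <= eps:
            raise ValueError(
                "mean signal sits on the optimum: cS is unidentifiable; use a "
                "shifted-state design with the signal displaced from thetaS"
            )
        estimates["cS"] = -gradients.estimates["betaNS"] / displacement
        se["cS"] = _ratio_se(
            estimates["cS"], gradients.se["betaNS"] / abs(displacement), rel
        )

    if second is not None and ("bA" in targets or "cA" in targets):
        grad2, state2 = second
        if abs(state.meanA - state2.meanA) <= eps:
            raise ValueError(
                "the two states have (near-)identical mean aggression; bA and "
                "cA cannot be separated - use states with distinct means"
            )
        M = np.array([[1.0, -state.meanA], [1.0, -state2.meanA]])
        beta = np.array(
            [gradients.estimates["betaNA"], grad2.estimates["betaNA"]]
        )
        bA, cA = np.linalg.solve(M, beta)
        rel2 = grad2.extra.get("fitness_scale_rel_se", 0.0)
        var_beta = np.array(
            [
                gradients.se["betaNA"] ** 2
                + (gradients.estimates["betaNA"] * rel) ** 2,
                grad2.se["betaNA"] ** 2
                + (grad2.estimates["betaNA"] * rel2) ** 2,
            ]
        )
        Minv = np.linalg.inv(M)
        var = (Minv**2) @ var_beta
        estimates["bA"], estimates["cA"] = float(bA), float(cA)
        se["bA"], se["cA"] = float(np.sqrt(var[0])), float(np.sqrt(var[1]))

    return EstimationResult(
        kind="contest_coefficients",
        estimates=estimates,
        se=se,
        n=gradients.n,
        r_squared=gradients.r_squared,
        condition_number=gradients.condition_number,
        extra={"thetaS": thetaS},
    )
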
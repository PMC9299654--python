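"""Flat key-value run configuration: parsing, validation, round-trip.

A config file is plain text, one ``key = value`` per line, ``#`` for
comments.  Model keys are the genetic (co)variances, the contest
coefficients, and the initial trait means; run keys control the
iteration and the individual-based simulator.  Every run writes back
the fully resolved configuration (defaults filled in) so a run can be
reproduced bit for bit from its output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import ContestParams, GeneticArchitecture, PopulationState
from .dynamics import DEFAULT_DIVERGENCE_BOUND, DEFAULT_MAX_GENERATIONS, DEFAULT_TOL

logger = logging.getLogger("agonistic")

#: keys that must be present in every config file
REQUIRED_KEYS = (
    "GSS",
    "GBB",
    "GAA",
    "GSB",
    "bA",
    "cA",
    "cB",
    "cS",
    "deltaAS",
)

#: optional keys and their defaults
OPTIONAL_KEYS = {
    "ESS": 0.0,
    "EBB": 0.0,
    "EAA": 0.0,
    "ESB": 0.0,
    "thetaS": 0.0,
    "w0": 1.0,
    "z0S": 0.0,
    "z0B": 0.0,
    "z0A": 0.0,
    "generations": float(DEFAULT_MAX_GENERATIONS),
    "n": 1000.0,
    "replicates": 1.0,
    "seed": 0.0,
    "tol": DEFAULT_TOL,
    "divergence_bound": DEFAULT_DIVERGENCE_BOUND,
}

_INT_KEYS = ("generations", "n", "replicates", "seed")


@dataclass
class RunConfig:
    """Fully resolved configuration for one reproducible run."""

    genetics: GeneticArchitecture
    params: ContestParams
    initial: PopulationState
    generations: int
    n: int
    replicates: int
    seed: int
    tol: float
    divergence_bound: float

    def as_dict(self) -> dict[str, float | int]:
        g, p, s = self.genetics, self.params, self.initial
        return {
            "GSS": g.GSS,
            "GBB": g.GBB,
            "GAA": g.GAA,
            "GSB": g.GSB,
            "ESS": g.ESS,
            "EBB": g.EBB,
            "EAA": g.EAA,
            "ESB": g.ESB,
            "bA": p.bA,
            "cA": p.cA,
            "cB": p.cB,
            "cS": p.cS,
            "thetaS": p.thetaS,
            "deltaAS": p.deltaAS,
            "w0": p.w0,
            "z0S": s.meanS,
            "z0B": s.meanB,
            "z0A": s.meanA,
            "generations": self.generations,
            "n": self.n,
            "replicates": self.replicates,
            "seed": self.seed,
            "tol": self.tol,
            "divergence_bound": self.divergence_bound,
        }

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# fully resolved run configuration\n")
            for key, value in self.as_dict().items():
                fh.write(f"{key} = {value!r}\n")


def _parse_lines(text: str, source: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{source}:{lineno}: cannot parse line {raw!r}")
            key, val = parts
        key, val = key.strip(), val.strip()
        known = set(REQUIRED_KEYS) | set(OPTIONAL_KEYS)
        if key not in known:
            raise ValueError(f"{source}:{lineno}: unknown configuration key {key!r}")
        if key in values:
            raise ValueError(f"{source}:{lineno}: duplicate key {key!r}")
        try:
            values[key] = float(val)
        except ValueError as exc:
            raise ValueError(
                f"{source}:{lineno}: value for {key!r} is not a number: {val!r}"
            ) from exc
    return values


def config_from_mapping(values: dict[str, float], source: str = "<config>") -> RunConfig:
    """Build a :class:`RunConfig` from parsed key-value pairs."""
    missing = [k for k in REQUIRED_KEYS if k not in values]
    if missing:
        raise ValueError(
            f"{source}: missing required configuration key(s): " + ", ".join(missing)
        )
    resolved = dict(OPTIONAL_KEYS)
    resolved.update(values)
    genetics = GeneticArchitecture(
        GSS=resolved["GSS"],
        GBB=resolved["GBB"],
        GAA=resolved["GAA"],
        GSB=resolved["GSB"],
        ESS=resolved["ESS"],
        EBB=resolved["EBB"],
        EAA=resolved["EAA"],
        ESB=resolved["ESB"],
    )
    params = ContestParams(
        bA=resolved["bA"],
        cA=resolved["cA"],
        cB=resolved["cB"],
        cS=resolved["cS"],
        thetaS=resolved["thetaS"],
        deltaAS=resolved["deltaAS"],
        w0=resolved["w0"],
    )
    initial = PopulationState(
        meanS=resolved["z0S"], meanB=resolved["z0B"], meanA=resolved["z0A"]
    )
    ints = {k: int(resolved[k]) for k in _INT_KEYS}
    return RunConfig(
        genetics=genetics,
        params=params,
        initial=initial,
        generations=ints["generations"],
        n=ints["n"],
        replicates=ints["replicates"],
        seed=ints["seed"],
        tol=resolved["tol"],
        divergence_bound=resolved["divergence_bound"],
    )


def load_config(path) -> RunConfig:
    """Parse and resolve a key-value config file."""
    with open(path) as fh:
        text = fh.read()
    return config_from_mapping(_parse_lines(text, str(path)), source=str(path))
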
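"""Flux balance analysis (FBA) and flux variability analysis (FVA).

The LP is  max fᵀv  s.t.  S·v = 0,  v_min ≤ v ≤ v_max.  FVA then minimizes
and maximizes each reaction flux over the near-optimal face: the objective
flux is confined to the window [γ·z*, z*], where γ ∈ (0, 1] is the
optimality fraction (γ = 1 reproduces exact fixing of the objective).

One solver (HiGHS via scipy.optimize.linprog) is pinned, with feasibility
tolerances of 1e-9, because solver choice measurably perturbs downstream
variable/sensitive counts.  Per-direction FVA failures are recorded in the
result rather than raised: failures at the edge of feasibility are a
diagnostic signal, not an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleModelError
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

SOLVER_NAME = "scipy-highs"
FEASIBILITY_TOL = 1e-9
#: default FVA interval-width threshold separating variable from stable
DEFAULT_THETA = 1e-6

_SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}

_STATUS_MAP = {
    0: "optimal",
    1: "numeric_failure",   # iteration limit
    2: "infeasible",
    3: "unbounded",
    4: "numeric_failure",
}


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its solver verdict."""

    fluxes: dict[str, float]
    objective_value: float
    solver_status: str

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FVAInterval:
    minimum: float
    maximum: float
    status_min: str
    status_max: str

    @property
    def ok(self) -> bool:
        return self.status_min == "optimal" and self.status_max == "optimal"

    @property
    def width(self) -> float:
        return self.maximum - self.minimum


@dataclass
class FVAResult:
    """Per-reaction flux intervals over the γ-relaxed optimal face."""

    gamma: float
    objective_value: float
    intervals: dict[str, FVAInterval]
    theta_var: float = DEFAULT_THETA
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, rid: str) -> FVAInterval:
        return self.intervals[rid]

    @property
    def n_failed(self) -> int:
        """Number of failed per-direction optimizations."""
        return sum(
            (iv.status_min != "optimal") + (iv.status_max != "optimal")
            for iv in self.intervals.values()
        )

    def variable_reactions(self, theta: float | None = None) -> list[str]:
        cls = classify_variable(self, self.theta_var if theta is None else theta)
        return [rid for rid, c in cls.items() if c == "variable"]

    def to_frame(self, theta: float | None = None):
        import pandas as pd

        cls = classify_variable(self, self.theta_var if theta is None else theta)
        rows = [
            {
                "reaction_id": rid,
                "min": iv.minimum,
                "max": iv.maximum,
                "width": iv.width,
                "status_min": iv.status_min,
                "status_max": iv.status_max,
                "variable": int(cls[rid] == "variable"),
            }
            for rid, iv in self.intervals.items()
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path, theta: float | None = None) -> None:
        self.to_frame(theta).to_csv(path, sep="\t", index=False,
                                    float_format="%.10g")


def _solve(c, S, bounds, sense: str):
    """Solve max/min cᵀv s.t. S·v = 0 and bounds; returns (status, x, obj)."""
    sign = -1.0 if sense == "maximize" else 1.0
    b_eq = np.zeros(S.shape[0])
    res = linprog(
        sign * c, A_eq=S, b_eq=b_eq, bounds=list(zip(*bounds)),
        method="highs", options=_SOLVER_OPTIONS,
    )
    status = _STATUS_MAP.get(res.status, "numeric_failure")
    obj = sign * res.fun if res.fun is not None else np.nan
    return status, res.x, obj


def solve_fba(model: MetabolicModel) -> FluxDistribution:
    """One optimal flux distribution (an arbitrary member of the optimal face).

    Infeasibility and unboundedness are reported through ``solver_status``,
    never raised.  Repeated calls on the same model are bit-identical: the
    solver, its parameters and the constraint ordering are all fixed.
    """
    model.validate()
    S, _ = model.stoichiometric_matrix()
    bounds = model.bounds_arrays()
    c = np.zeros(len(model.reactions))
    c[model.objective_index()] = 1.0
    status, x, obj = _solve(c, S, bounds, model.objective_sense)
    if status != "optimal" or x is None:
        return FluxDistribution({}, np.nan, status)
    return FluxDistribution(
        dict(zip(model.reaction_ids, map(float, x))), float(obj), "optimal"
    )


def _objective_window(z: float, gamma: float, sense: str) -> tuple[float, float]:
    """Allowed objective-flux interval at optimality fraction γ."""
    slack = (1.0 - gamma) * abs(z)
    if sense == "maximize":
        return z - slack, z
    return z, z + slack


def run_fva(
    model: MetabolicModel,
    gamma: float = 1.0,
    reactions: list[str] | None = None,
    theta_var: float = DEFAULT_THETA,
) -> FVAResult:
    """FVA over the γ-relaxed optimal face.

    The objective reaction's bounds are replaced by the window
    [γ·z*, z*] (maximization; mirrored for minimization or z* < 0), so γ = 1
    is exactly the fixed-objective face.  Each requested reaction is then
    independently minimized and maximized; per-direction failures are stored
    in the per-reaction statuses.

    Raises :class:`InfeasibleModelError` only if the model is infeasible
    before any relaxation.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    ref = solve_fba(model)
    if ref.solver_status != "optimal":
        raise InfeasibleModelError(
            f"model {model.model_id!r} not solvable before FVA "
            f"(status {ref.solver_status})",
            status=ref.solver_status,
        )
    z = ref.objective_value
    lo_w, hi_w = _objective_window(z, gamma, model.objective_sense)

    S, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    lb, ub = lb.copy(), ub.copy()
    oi = model.objective_index()
    if lb[oi] == ub[oi]:
        lb[oi], ub[oi] = lo_w, hi_w          # the fixing *is* the window
    else:
        lb[oi], ub[oi] = max(lb[oi], lo_w), min(ub[oi], hi_w)

    rids = model.reaction_ids
    targets = rids if reactions is None else list(reactions)
    idx = {r: i for i, r in enumerate(rids)}
    n = len(rids)
    intervals: dict[str, FVAInterval] = {}
    for rid in targets:
        c = np.zeros(n)
        c[idx[rid]] = 1.0
        stat_min, x_min, vmin = _solve(c, S, (lb, ub), "minimize")
        stat_max, x_max, vmax = _solve(c, S, (lb, ub), "maximize")
        if stat_min != "optimal" or stat_max != "optimal":
            logger.warning(
                "FVA optimization failed for %s (min=%s, max=%s)",
                rid, stat_min, stat_max,
            )
        intervals[rid] = FVAInterval(
            float(vmin) if stat_min == "optimal" else np.nan,
            float(vmax) if stat_max == "optimal" else np.nan,
            stat_min, stat_max,
        )
    return FVAResult(
        gamma=gamma, objective_value=float(z), intervals=intervals,
        theta_var=theta_var,
        metadata={
            "solver": SOLVER_NAME,
            "feasibility_tolerance": FEASIBILITY_TOL,
            "gamma": gamma,
            "theta_var": theta_var,
        },
    )


def classify_variable(
    fva: FVAResult, theta: float = DEFAULT_THETA
) -> dict[str, str]:
    """Label each reaction ``variable`` / ``stable`` / ``undetermined``.

    Variable means both FVA directions solved and the interval width exceeds
    ``theta``; a failed direction yields ``undetermined`` (neither class).
    """
    out = {}
    for rid, iv in fva.intervals.items():
        if not iv.ok:
            out[rid] = "undetermined"
        elif iv.width > theta:
            out[rid] = "variable"
        else:
            out[rid] = "stable"
    return out
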
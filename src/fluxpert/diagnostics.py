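"""Edge-of-feasibility scans and a simplified flux-module partition.

When a parameter (classically the non-growth-associated ATP maintenance
flux, ATPm) sits exactly at the edge of the feasible region, FVA
optimizations start to fail and the *apparent* solution space collapses —
a numerical artefact, not biology.  ``scan_parameter`` sweeps a reaction's
feasible interval and flags grid points showing that signature; the
remedy mirrors practice: relax one bound by a small amount (default 0.05
flux units) and re-scan.

``partition_modules`` summarizes the optimal face as flux modules: maximal
sets of variable reactions whose fluxes co-vary as one linearly independent
block.  The partition is computed from the null space of the stoichiometric
system augmented with the objective row, restricted to variable-reaction
coordinates, canonicalized by reduced row echelon form so the support
pattern does not depend on an arbitrary basis choice.  This is a simplified
summary in the spirit of vertex/ray/lineality decompositions, not a
reimplementation of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .errors import InputError
from .lp_core import DEFAULT_THETA, FVAResult, classify_variable, run_fva
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

_RREF_TOL = 1e-9


@dataclass
class ScanPoint:
    value: float
    feasible: bool
    n_variable: int
    n_modules: int
    n_failed_fva_optimizations: int


@dataclass
class ScanResult:
    """A parameter sweep with per-point solution-space size measures."""

    scanned_reaction: str
    points: list[ScanPoint]
    flags: list[int] = field(default_factory=list)   # grid indices, edge artefact

    @property
    def grid(self) -> list[float]:
        return [p.value for p in self.points]

    def to_frame(self):
        import pandas as pd

        flagged = set(self.flags)
        return pd.DataFrame(
            [
                {
                    "value": p.value,
                    "feasible": int(p.feasible),
                    "n_variable": p.n_variable,
                    "n_modules": p.n_modules,
                    "n_failed": p.n_failed_fva_optimizations,
                    "edge_flag": int(i in flagged),
                }
                for i, p in enumerate(self.points)
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class ModulePartition:
    """Disjoint flux modules covering the variable set (minus undetermined)."""

    modules: list[list[str]]
    undetermined: set[str] = field(default_factory=set)
    note: str = ""

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def to_lines(self) -> str:
        return "\n".join(",".join(m) for m in self.modules) + ("\n" if self.modules else "")


def _rref(M: np.ndarray, tol: float = _RREF_TOL) -> np.ndarray:
    """Reduced row echelon form with partial pivoting; sub-tol entries zeroed."""
    A = M.astype(float).copy()
    nr, nc = A.shape
    row = 0
    for col in range(nc):
        if row >= nr:
            break
        piv = row + int(np.argmax(np.abs(A[row:, col])))
        if abs(A[piv, col]) <= tol:
            continue
        A[[row, piv]] = A[[piv, row]]
        A[row] /= A[row, col]
        for r in range(nr):
            if r != row:
                A[r] -= A[r, col] * A[row]
        row += 1
    A[np.abs(A) <= tol] = 0.0
    return A


def partition_modules(
    model: MetabolicModel,
    fva: FVAResult,
    theta: float = DEFAULT_THETA,
) -> ModulePartition:
    """Partition the variable reactions into co-varying flux modules.

    Directions of the optimal face satisfy S·d = 0 and fᵀd = 0 with every
    stable coordinate forced to zero.  The null-space basis restricted to
    variable coordinates is canonicalized by RREF; two reactions share a
    module iff they co-occur in some canonical basis vector's support
    (transitively).  Variable reactions in no support are reported as
    undetermined.  Rank-deficiency failures are reported in ``note``, not
    raised.
    """
    var_class = classify_variable(fva, theta)
    variable = [rid for rid in model.reaction_ids
                if var_class.get(rid) == "variable"]
    if not variable:
        return ModulePartition([], set())
    S, _ = model.stoichiometric_matrix()
    c = np.zeros(len(model.reactions))
    c[model.objective_index()] = 1.0
    A = np.vstack([S, c])
    col = {rid: j for j, rid in enumerate(model.reaction_ids)}
    Av = A[:, [col[r] for r in variable]]
    try:
        N = null_space(Av)
    except np.linalg.LinAlgError as exc:            # pragma: no cover - rare
        logger.warning("null-space computation failed: %s", exc)
        return ModulePartition([], set(variable), note=f"rank failure: {exc}")
    if N.size == 0:
        return ModulePartition([], set(variable),
                               note="no free directions among variable reactions")
    B = _rref(N.T)
    supports = [set(np.nonzero(row)[0]) for row in B if np.any(row)]

    parent = list(range(len(variable)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for sup in supports:
        sup = sorted(sup)
        for j in sup[1:]:
            parent[find(j)] = find(sup[0])
    in_support = set().union(*supports) if supports else set()
    groups: dict[int, list[str]] = {}
    for i, rid in enumerate(variable):
        if i not in in_support:
            continue
        groups.setdefault(find(i), []).append(rid)
    modules = sorted((sorted(g) for g in groups.values()), key=lambda m: m[0])
    undetermined = {variable[i] for i in range(len(variable)) if i not in in_support}
    if undetermined:
        logger.warning("variable reactions outside every module support: %s",
                       sorted(undetermined))
    return ModulePartition(modules, undetermined)


def scan_parameter(
    model: MetabolicModel,
    reaction_id: str,
    n_points: int = 11,
    gamma: float = 1.0,
    theta: float = DEFAULT_THETA,
    grid: list[float] | None = None,
) -> ScanResult:
    """Sweep a reaction's feasible interval and measure the solution space.

    The feasible interval comes from FVA with the objective fixed; the grid
    is ``n_points`` equally spaced values including both endpoints (or an
    explicit ``grid``).  At each value the reaction is fixed (lb = ub), FVA
    re-run, and variable/module/failure counts recorded.  A grid point is
    flagged as an edge artefact when any FVA optimization fails there or its
    variable count drops below half the median of the interior points.
    """
    obj = model.reaction(model.objective_reaction)
    if obj.lower_bound != obj.upper_bound:
        raise InputError("scan requires the objective flux fixed (lb = ub)")
    model.reaction(reaction_id)
    if grid is None:
        base = run_fva(model, gamma=gamma, reactions=[reaction_id])
        iv = base[reaction_id]
        if not iv.ok:
            raise InputError(
                f"cannot determine feasible interval of {reaction_id!r} "
                f"(statuses {iv.status_min}/{iv.status_max})"
            )
        if iv.width <= theta:
            raise InputError(
                f"reaction {reaction_id!r} has a zero-width feasible interval: "
                "nothing to scan"
            )
        grid = list(np.linspace(iv.minimum, iv.maximum, n_points))
    else:
        grid = [float(v) for v in grid]
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise InputError("explicit grid must be strictly increasing")

    points: list[ScanPoint] = []
    for value in grid:
        fixed = model.copy()
        r = fixed.reaction(reaction_id)
        r.lower_bound = r.upper_bound = value
        try:
            fva = run_fva(fixed, gamma=gamma, theta_var=theta)
        except InputError:
            raise
        except Exception:
            points.append(ScanPoint(value, False, 0, 0, 0))
            continue
        n_var = len(fva.variable_reactions(theta))
        part = partition_modules(fixed, fva, theta)
        points.append(
            ScanPoint(value, True, n_var, len(part.modules), fva.n_failed)
        )

    interior = [p.n_variable for p in points[1:-1] if p.feasible]
    med = float(np.median(interior)) if interior else 0.0
    flags = [
        i for i, p in enumerate(points)
        if p.feasible
        and (p.n_failed_fva_optimizations > 0 or p.n_variable < 0.5 * med)
    ]
    if flags:
        logger.warning("edge artefact flagged at grid indices %s of scan on %s",
                       flags, reaction_id)
    return ScanResult(reaction_id, points, flags)


def relax_and_retry(
    model: MetabolicModel, reaction_id: str, epsilon: float = 0.05
) -> MetabolicModel:
    """Relax a reaction's lower bound by ``epsilon`` (uptake-side slack).

    The standard remedy for edge-of-feasibility artefacts: nudging one bound
    restores slack so FVA optimizations succeed again at the previously
    flagged parameter value.  Returns a modified copy; the change is logged
    as a remediation.
    """
    out = model.copy()
    r = out.reaction(reaction_id)
    r.lower_bound -= epsilon
    if epsilon != 0.0:
        logger.warning(
            "remediation: lower bound of %s relaxed by %g to %g",
            reaction_id, epsilon, r.lower_bound,
        )
    return out
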
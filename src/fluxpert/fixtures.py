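"""Synthetic test networks with closed-form solution-space oracles.

Every generator returns a :class:`FixtureBundle`: a small metabolic model
plus the exactly known geometry of its optimal face — the LP optimum, the
fixed-objective FVA interval of every reaction, the variable count and the
flux-module partition.  ``brute_force_fva`` provides the independent oracle:
exhaustive vertex enumeration of the bounded flux polytope, exact up to
linear-algebra round-off, feasible only for tiny networks (≤ 12 reactions)
and therefore never a substitute for the LP path it checks.

Generation is fully deterministic; no randomness enters topology or bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .errors import InputError
from .model_core import BOUND_CAP, MetabolicModel, Metabolite, Reaction

_VERTEX_TOL = 1e-9
_MAX_REACTIONS = 12


@dataclass
class FixtureBundle:
    """A toy model together with its hand-derivable solution-space facts."""

    model: MetabolicModel
    #: LP optimum of the unfixed model
    optimum: float
    #: fixed-objective (γ=1) FVA interval per reaction
    fva_intervals: dict[str, tuple[float, float]]
    #: number of variable reactions at θ = 1e-6 with the objective fixed
    n_variable: int
    #: expected flux-module partition (list of reaction-id sets)
    modules: list[set[str]]
    #: free-form notes: branch-fraction formulas, feasible-interval formulas
    notes: dict = field(default_factory=dict)


def _model(model_id, mets, rxns, stoich, objective) -> MetabolicModel:
    m = MetabolicModel(
        model_id=model_id,
        metabolites=[Metabolite(i, i.upper()) for i in mets],
        reactions=rxns,
        stoichiometry=stoich,
        objective_reaction=objective,
    )
    m.validate()
    return m


def make_chain(n_steps: int = 2, uptake_ub: float = 10.0) -> FixtureBundle:
    """Linear pathway ∅→M₁→…→Mₙ→∅ — the null case: a unique optimum.

    ``n_steps`` internal metabolites give ``n_steps + 1`` reactions.  With
    the terminal exchange maximized, every flux is forced to ``uptake_ub``:
    all FVA widths are zero, no variable reactions, no modules.
    """
    if n_steps < 1 or uptake_ub <= 0:
        raise InputError("need n_steps >= 1 and uptake_ub > 0")
    mets = [f"M{i}" for i in range(1, n_steps + 1)]
    rxns = [Reaction("R_in", "uptake", 0.0, uptake_ub)]
    stoich = {("M1", "R_in"): 1.0}
    for i in range(1, n_steps):
        rid = f"R_{i}{i + 1}"
        rxns.append(Reaction(rid, "", 0.0, BOUND_CAP))
        stoich[(f"M{i}", rid)] = -1.0
        stoich[(f"M{i + 1}", rid)] = 1.0
    rxns.append(Reaction("R_out", "export", 0.0, BOUND_CAP))
    stoich[(f"M{n_steps}", "R_out")] = -1.0
    model = _model(f"chain_{n_steps}", mets, rxns, stoich, "R_out")
    u = uptake_ub
    return FixtureBundle(
        model=model,
        optimum=u,
        fva_intervals={r.id: (u, u) for r in rxns},
        n_variable=0,
        modules=[],
    )


_PATH_LETTERS = "bcefghijklm"      # 'd' is the sink metabolite


def make_diamond(n_parallel_paths: int = 2, uptake_ub: float = 10.0) -> FixtureBundle:
    """n disjoint 2-reaction paths A→Xᵢ→D: the minimal alternate-optima face.

    Uptake and export are pinned at the optimum; the split of flux across
    the paths is entirely free, so every path reaction has interval
    [0, uptake_ub], all 2n of them sensitive to perturbation and co-varying
    in a single flux module.  Metabolite A is an n-way branching point.
    """
    if n_parallel_paths < 2:
        raise InputError("need n_parallel_paths >= 2")
    if n_parallel_paths > len(_PATH_LETTERS):
        raise InputError("too many parallel paths")
    letters = _PATH_LETTERS[:n_parallel_paths]
    mets = ["A"] + [l.upper() for l in letters] + ["D"]
    rxns = [Reaction("R_in", "uptake", 0.0, uptake_ub)]
    stoich: dict[tuple[str, str], float] = {("A", "R_in"): 1.0}
    path_rxns: list[str] = []
    for l in letters:
        r1, r2 = f"R_a{l}", f"R_{l}d"
        rxns.append(Reaction(r1, "", 0.0, BOUND_CAP))
        rxns.append(Reaction(r2, "", 0.0, BOUND_CAP))
        stoich[("A", r1)] = -1.0
        stoich[(l.upper(), r1)] = 1.0
        stoich[(l.upper(), r2)] = -1.0
        stoich[("D", r2)] = 1.0
        path_rxns += [r1, r2]
    rxns.append(Reaction("R_out", "export", 0.0, BOUND_CAP))
    stoich[("D", "R_out")] = -1.0
    model = _model(f"diamond_{n_parallel_paths}", mets, rxns, stoich, "R_out")
    u = uptake_ub
    intervals = {rid: (0.0, u) for rid in path_rxns}
    intervals["R_in"] = intervals["R_out"] = (u, u)
    return FixtureBundle(
        model=model,
        optimum=u,
        fva_intervals=intervals,
        n_variable=2 * n_parallel_paths,
        modules=[set(path_rxns)],
        notes={
            "branch_metabolite": "A",
            "branch_reactions": [f"R_a{l}" for l in letters],
            "branch_fraction": "fraction of path i = v(R_a{i})/uptake_ub",
        },
    )


def make_double_diamond(uptake_ub: float = 10.0) -> FixtureBundle:
    """Two diamonds in series: two independent flux modules of four.

    A→(B|C)→D feeds D→(E|F)→G; the split in one diamond is linearly
    independent of the split in the other, so fixing a reaction of the first
    leaves the second's FVA intervals unchanged.
    """
    u = uptake_ub
    mets = list("ABCDEFG")
    wiring = [
        ("R_in", None, "A"),
        ("R_ab", "A", "B"), ("R_bd", "B", "D"),
        ("R_ac", "A", "C"), ("R_cd", "C", "D"),
        ("R_de", "D", "E"), ("R_eg", "E", "G"),
        ("R_df", "D", "F"), ("R_fg", "F", "G"),
        ("R_out", "G", None),
    ]
    rxns, stoich = [], {}
    for rid, src, dst in wiring:
        ub = u if rid == "R_in" else BOUND_CAP
        rxns.append(Reaction(rid, "", 0.0, ub))
        if src:
            stoich[(src, rid)] = -1.0
        if dst:
            stoich[(dst, rid)] = 1.0
    model = _model("double_diamond", mets, rxns, stoich, "R_out")
    block1 = {"R_ab", "R_bd", "R_ac", "R_cd"}
    block2 = {"R_de", "R_eg", "R_df", "R_fg"}
    intervals = {rid: (0.0, u) for rid in block1 | block2}
    for rid in ("R_in", "R_out"):
        intervals[rid] = (u, u)
    return FixtureBundle(
        model=model, optimum=u, fva_intervals=intervals,
        n_variable=8, modules=[block1, block2],
    )


def make_atp_toy(
    uptake_ub: float = 10.0, yield_low: float = 1.0, yield_high: float = 2.0
) -> FixtureBundle:
    """Glucose-like uptake, two fermentation routes with different ATP
    yields, an ATP-maintenance drain and a biomass-like ATP sink.

    The exchange follows the standard sign convention (uptake = negative
    flux, lower bound −uptake_ub).  Maximal objective with the maintenance
    lower bound at m is yield_high·uptake_ub − m.  With the objective fixed
    at z, the feasible maintenance interval is [0, yield_high·uptake_ub − z];
    at its right endpoint all fluxes are forced through the high-yield route
    at full uptake — zero variable reactions, the edge-of-feasibility
    signature.
    """
    if not (0 < yield_low < yield_high):
        raise InputError("need 0 < yield_low < yield_high")
    u, yl, yh = uptake_ub, yield_low, yield_high
    mets = ["glc", "atp"]
    rxns = [
        Reaction("EX_glc", "glucose exchange", -u, 0.0, reversible=True),
        Reaction("R_ferm_lo", "low-yield fermentation", 0.0, BOUND_CAP),
        Reaction("R_ferm_hi", "high-yield fermentation", 0.0, BOUND_CAP),
        Reaction("R_atpm", "ATP maintenance", 0.0, BOUND_CAP),
        Reaction("R_bio", "biomass ATP demand", 0.0, BOUND_CAP),
    ]
    stoich = {
        ("glc", "EX_glc"): -1.0,
        ("glc", "R_ferm_lo"): -1.0, ("atp", "R_ferm_lo"): yl,
        ("glc", "R_ferm_hi"): -1.0, ("atp", "R_ferm_hi"): yh,
        ("atp", "R_atpm"): -1.0,
        ("atp", "R_bio"): -1.0,
    }
    model = _model("atp_toy", mets, rxns, stoich, "R_bio")
    z_max = yh * u
    return FixtureBundle(
        model=model,
        optimum=z_max,
        # with the objective fixed at the optimum everything is forced
        fva_intervals={
            "EX_glc": (-u, -u), "R_ferm_lo": (0.0, 0.0),
            "R_ferm_hi": (u, u), "R_atpm": (0.0, 0.0), "R_bio": (z_max, z_max),
        },
        n_variable=0,
        modules=[],
        notes={
            "scan_reaction": "R_atpm",
            "feasible_atpm_interval": "[0, yield_high*uptake_ub - z] for "
                                      "objective fixed at z",
            "relax_reaction": "EX_glc",
        },
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _enumerate_vertices(A: np.ndarray, b: np.ndarray,
                        lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """All vertices of {x : A x = b, lb ≤ x ≤ ub} by bound-subset fixing.

    At a vertex, n − rank(A) coordinates sit at a bound; every such subset ×
    bound combination yields a square-solvable linear system whose solution
    is kept if it is feasible within 1e-9.  Exact for bounded polytopes.
    """
    n = A.shape[1]
    if np.any(~np.isfinite(lb)) or np.any(~np.isfinite(ub)):
        raise InputError("vertex enumeration needs finite bounds")
    rank = int(np.linalg.matrix_rank(A, tol=1e-10)) if A.size else 0
    n_fix = n - rank
    vertices: list[np.ndarray] = []
    for subset in combinations(range(n), n_fix):
        rest = [j for j in range(n) if j not in subset]
        Ar = A[:, rest]
        if rest and np.linalg.matrix_rank(Ar, tol=1e-10) < len(rest):
            continue
        for corner in product(*[(lb[j], ub[j]) for j in subset]):
            x = np.empty(n)
            x[list(subset)] = corner
            rhs = b - (A[:, list(subset)] @ np.array(corner) if subset else 0.0)
            if rest:
                sol, *_ = np.linalg.lstsq(Ar, rhs, rcond=None)
                x[rest] = sol
            if np.max(np.abs(A @ x - b), initial=0.0) > _VERTEX_TOL:
                continue
            if np.any(x < lb - _VERTEX_TOL) or np.any(x > ub + _VERTEX_TOL):
                continue
            vertices.append(np.clip(x, lb, ub))
    if not vertices:
        return np.empty((0, n))
    V = np.array(vertices)
    # deduplicate
    keep: list[int] = []
    for i in range(len(V)):
        if all(np.max(np.abs(V[i] - V[j])) > 1e-8 for j in keep):
            keep.append(i)
    return V[keep]


def _lp_data(model: MetabolicModel):
    if len(model.reactions) > _MAX_REACTIONS:
        raise InputError(
            f"brute-force oracle capped at {_MAX_REACTIONS} reactions; "
            f"model has {len(model.reactions)}"
        )
    S, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(model.reactions))
    c[model.objective_index()] = 1.0
    return S, lb, ub, c


def brute_force_optimum(model: MetabolicModel) -> float:
    """LP optimum by exhaustive vertex enumeration (tiny models only)."""
    S, lb, ub, c = _lp_data(model)
    V = _enumerate_vertices(S, np.zeros(S.shape[0]), lb, ub)
    if V.shape[0] == 0:
        raise InputError("no feasible vertex found")
    vals = V @ c
    return float(vals.max() if model.objective_sense == "maximize" else vals.min())


def brute_force_fva(
    model: MetabolicModel, fixed_objective_value: float | None = None
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux intervals over the fixed-objective face, by vertex
    enumeration.

    ``fixed_objective_value`` defaults to the brute-force optimum.  The face
    polytope {S·v = 0, fᵀv = z, bounds} is bounded (all bounds finite after
    the ±1000 clamp), so coordinate-wise min/max over its vertices is exact.
    """
    S, lb, ub, c = _lp_data(model)
    z = (brute_force_optimum(model) if fixed_objective_value is None
         else float(fixed_objective_value))
    A = np.vstack([S, c])
    b = np.concatenate([np.zeros(S.shape[0]), [z]])
    V = _enumerate_vertices(A, b, lb, ub)
    if V.shape[0] == 0:
        raise InputError(
            f"no vertex attains objective {z} — face is empty or z infeasible"
        )
    return {
        rid: (float(V[:, j].min()), float(V[:, j].max()))
        for j, rid in enumerate(model.reaction_ids)
    }
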
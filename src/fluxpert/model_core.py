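"""Metabolic-model data types, readers/writers and constraint integration.

A :class:`MetabolicModel` is the LP substrate of constraint-based analysis:
the stoichiometric matrix ``S`` (rows = internal metabolites), per-reaction
flux bounds in mmol·gDW⁻¹·h⁻¹, and a single-reaction objective.  Bounds with
magnitude above 1000 are treated as infinite and clamped: ±1000 is the
conventional infinity proxy in genome-scale models of this kind.

Constraint integration follows the step-wise experimental protocol used for
lactic-acid-bacteria models: medium composition (explicit exchange bounds),
measured uptake/secretion rates with a relative tolerance band (default ±20%
around the measured value), proteome-absent reactions forced to zero flux,
and explicit flux fixings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

#: canonical infinity proxy for flux bounds (mmol·gDW⁻¹·h⁻¹)
BOUND_CAP = 1000.0


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    boundary: bool = False


@dataclass
class Reaction:
    id: str
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = BOUND_CAP
    reversible: bool = False


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds and objective of a constraint-based model."""

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    #: (metabolite id, reaction id) -> stoichiometric coefficient
    stoichiometry: dict[tuple[str, str], float]
    objective_reaction: str
    objective_sense: str = "maximize"

    # -- lookups ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise InputError(f"unknown reaction id {rid!r} in model {self.model_id!r}")

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise InputError(f"unknown metabolite id {mid!r} in model {self.model_id!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[replace(r) for r in self.reactions],
            stoichiometry=dict(self.stoichiometry),
            objective_reaction=self.objective_reaction,
            objective_sense=self.objective_sense,
        )

    # -- LP view ---------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense ``S`` over internal (non-boundary) metabolites.

        Returns ``(S, met_ids)`` with ``S[i, j]`` the coefficient of internal
        metabolite ``met_ids[i]`` in reaction ``self.reactions[j]``.
        """
        internal = [m.id for m in self.metabolites if not m.boundary]
        mi = {m: i for i, m in enumerate(internal)}
        ri = {r.id: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(internal), len(self.reactions)))
        for (mid, rid), coef in self.stoichiometry.items():
            if mid in mi:
                S[mi[mid], ri[rid]] = coef
        return S, internal

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def objective_index(self) -> int:
        return self.reaction_ids.index(self.objective_reaction)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise InputError(f"duplicate reaction id(s): {', '.join(dup)}")
        mids = set(self.metabolite_ids)
        if len(mids) != len(self.metabolites):
            raise InputError("duplicate metabolite ids")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise InputError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            if abs(r.lower_bound) > BOUND_CAP or abs(r.upper_bound) > BOUND_CAP:
                raise InputError(
                    f"reaction {r.id!r}: bounds exceed the ±{BOUND_CAP:g} cap"
                )
        if self.objective_reaction not in rids:
            raise InputError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        if self.objective_sense not in ("maximize", "minimize"):
            raise InputError(f"bad objective sense {self.objective_sense!r}")
        rset = set(rids)
        for mid, rid in self.stoichiometry:
            if mid not in mids:
                raise InputError(f"stoichiometry references unknown metabolite {mid!r}")
            if rid not in rset:
                raise InputError(f"stoichiometry references unknown reaction {rid!r}")


def clamp_bounds(model: MetabolicModel) -> MetabolicModel:
    """Clamp bound magnitudes above ``BOUND_CAP`` to ±``BOUND_CAP`` (warn)."""
    for r in model.reactions:
        for attr in ("lower_bound", "upper_bound"):
            v = getattr(r, attr)
            if abs(v) > BOUND_CAP or not np.isfinite(v):
                clamped = float(np.clip(v, -BOUND_CAP, BOUND_CAP))
                if not np.isfinite(v):
                    clamped = BOUND_CAP if v > 0 else -BOUND_CAP
                logger.warning(
                    "clamping %s of reaction %s from %g to %g",
                    attr, r.id, v, clamped,
                )
                setattr(r, attr, clamped)
    return model


# ---------------------------------------------------------------------------
# constraint sets
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Experimental constraints applied to a model in a fixed precedence.

    ``medium`` entries overwrite exchange bounds outright; ``measured_rates``
    map a signed measured exchange flux *v_exp* (negative = uptake) to the
    tolerance band ``[min((1∓t)·v_exp), max((1±t)·v_exp)]``; reactions in
    ``absent_reactions`` (protein not detected) are closed to zero flux;
    ``fixed_fluxes`` pin a reaction at one value.  Later groups override
    earlier ones: medium < measured < absent < fixed.
    """

    medium: dict[str, tuple[float, float]] = field(default_factory=dict)
    measured_rates: dict[str, float] = field(default_factory=dict)
    rate_tolerance: float = 0.20
    absent_reactions: set[str] = field(default_factory=set)
    fixed_fluxes: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.rate_tolerance < 1.0):
            raise InputError(
                f"rate_tolerance must be in [0, 1), got {self.rate_tolerance}"
            )

    def is_empty(self) -> bool:
        return not (
            self.medium or self.measured_rates
            or self.absent_reactions or self.fixed_fluxes
        )


def read_constraints_tsv(path) -> ConstraintSet:
    """Read a constraint table.

    Columns: ``reaction_id  kind  value  lb  ub`` with
    ``kind`` ∈ {medium, measured, absent, fixed}; ``value`` is used for
    measured/fixed rows, ``lb``/``ub`` for medium rows.  Empty cells allowed
    where a column does not apply.
    """
    cs = ConstraintSet()
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return cs
    header = lines[0].split("\t")
    expected = ["reaction_id", "kind", "value", "lb", "ub"]
    if [h.strip() for h in header[:5]] != expected:
        raise InputError(
            f"{path}: bad constraint header {header!r}, expected {expected}"
        )
    for ln in lines[1:]:
        parts = (ln.split("\t") + ["", "", ""])[:5]
        rid, kind, value, lb, ub = (p.strip() for p in parts)
        if kind == "medium":
            cs.medium[rid] = (float(lb), float(ub))
        elif kind == "measured":
            cs.measured_rates[rid] = float(value)
        elif kind == "absent":
            cs.absent_reactions.add(rid)
        elif kind == "fixed":
            cs.fixed_fluxes[rid] = float(value)
        else:
            raise InputError(f"{path}: unknown constraint kind {kind!r}")
    return cs


def apply_constraints(model: MetabolicModel, cs: ConstraintSet) -> MetabolicModel:
    """Return a new model with ``cs`` integrated.

    Application order is medium, measured rates, absent reactions, fixed
    fluxes; each later step overrides earlier ones and every override is
    logged.  Idempotent: all steps set absolute bounds.
    """
    cs.validate()
    out = model.copy()
    known = set(out.reaction_ids)
    for group in (cs.medium, cs.measured_rates, cs.absent_reactions, cs.fixed_fluxes):
        for rid in group:
            if rid not in known:
                raise InputError(f"constraint references unknown reaction {rid!r}")

    touched: dict[str, str] = {}

    def _set(rid: str, lo: float, hi: float, step: str) -> None:
        r = out.reaction(rid)
        if rid in touched:
            logger.warning(
                "constraint override: %s bounds set by %s then overridden by %s",
                rid, touched[rid], step,
            )
        touched[rid] = step
        r.lower_bound, r.upper_bound = lo, hi

    for rid, (lo, hi) in cs.medium.items():
        _set(rid, lo, hi, "medium")
    t = cs.rate_tolerance
    for rid, v_exp in cs.measured_rates.items():
        lo, hi = sorted(((1.0 - t) * v_exp, (1.0 + t) * v_exp))
        _set(rid, lo, hi, "measured")
    for rid in sorted(cs.absent_reactions):
        _set(rid, 0.0, 0.0, "absent")
    for rid, v in cs.fixed_fluxes.items():
        _set(rid, v, v, "fixed")

    for r in out.reactions:
        if r.lower_bound > r.upper_bound:
            raise InputError(
                f"constraints leave reaction {r.id!r} with empty bound interval "
                f"[{r.lower_bound}, {r.upper_bound}]"
            )
    return out


def fix_objective_flux(model: MetabolicModel, value: float) -> MetabolicModel:
    """Pin the objective reaction at ``value`` (lb = ub = value)."""
    out = model.copy()
    r = out.reaction(out.objective_reaction)
    if not (r.lower_bound - 1e-12 <= value <= r.upper_bound + 1e-12):
        raise InputError(
            f"objective value {value} outside current bounds "
            f"[{r.lower_bound}, {r.upper_bound}] of {r.id!r}"
        )
    r.lower_bound = r.upper_bound = value
    return out


# ---------------------------------------------------------------------------
# toy-model TSV format
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:([0-9.eE+-]+)\s+)?(\S+)$")


def _parse_side(side: str) -> list[tuple[float, str]]:
    side = side.strip()
    if not side:
        return []
    terms = []
    for chunk in side.split(" + "):
        m = _TERM_RE.match(chunk.strip())
        if not m:
            raise InputError(f"cannot parse formula term {chunk!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        terms.append((coef, m.group(2)))
    return terms


def _format_side(terms: list[tuple[str, float]]) -> str:
    out = []
    for mid, coef in terms:
        out.append(mid if coef == 1.0 else f"{_fmt(coef)} {mid}")
    return " + ".join(out)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def read_toy_model(path) -> MetabolicModel:
    """Read the two-section TSV toy format.

    Sections ``# metabolites`` (id, name, compartment, boundary 0/1) and
    ``# reactions`` (id, name, lb, ub, objective 0/1, formula).  Formulas use
    ``A + 2 B -> C`` with ``<=>`` marking reversible reactions; an empty side
    denotes exchange with the environment.  Reaction order in the file is the
    model's reaction order.
    """
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    stoich: dict[tuple[str, str], float] = {}
    objective: str | None = None
    section = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                tag = line.lstrip("#").strip().lower()
                if tag not in ("metabolites", "reactions"):
                    raise InputError(f"{path}:{lineno}: unknown section {tag!r}")
                section = tag
                continue
            parts = line.split("\t")
            if section == "metabolites":
                if len(parts) != 4:
                    raise InputError(f"{path}:{lineno}: metabolite row needs 4 columns")
                mid, name, comp, boundary = parts
                mets.append(Metabolite(mid, name, comp, boundary.strip() == "1"))
            elif section == "reactions":
                if len(parts) != 6:
                    raise InputError(f"{path}:{lineno}: reaction row needs 6 columns")
                rid, name, lb, ub, obj, formula = parts
                if any(r.id == rid for r in rxns):
                    raise InputError(f"{path}:{lineno}: duplicate reaction id {rid!r}")
                if "<=>" in formula:
                    left, right = formula.split("<=>", 1)
                    reversible = True
                elif "->" in formula:
                    left, right = formula.split("->", 1)
                    reversible = False
                else:
                    raise InputError(f"{path}:{lineno}: formula lacks an arrow")
                declared = {m.id for m in mets}
                for coef, mid in _parse_side(left):
                    if mid not in declared:
                        raise InputError(
                            f"{path}:{lineno}: metabolite {mid!r} not declared"
                        )
                    stoich[(mid, rid)] = stoich.get((mid, rid), 0.0) - coef
                for coef, mid in _parse_side(right):
                    if mid not in declared:
                        raise InputError(
                            f"{path}:{lineno}: metabolite {mid!r} not declared"
                        )
                    stoich[(mid, rid)] = stoich.get((mid, rid), 0.0) + coef
                rxns.append(Reaction(rid, name, float(lb), float(ub), reversible))
                if obj.strip() == "1":
                    if objective is not None:
                        raise InputError(f"{path}:{lineno}: second objective reaction")
                    objective = rid
            else:
                raise InputError(f"{path}:{lineno}: content before any section header")
    if objective is None:
        raise InputError(f"{path}: no objective reaction flagged")
    model = MetabolicModel(
        model_id=str(path), metabolites=mets, reactions=rxns,
        stoichiometry=stoich, objective_reaction=objective,
    )
    clamp_bounds(model)
    model.validate()
    return model


def write_toy_model(model: MetabolicModel, path) -> None:
    """Write the canonical toy TSV; re-reading reproduces the model."""
    lines = ["# metabolites"]
    for m in model.metabolites:
        lines.append(f"{m.id}\t{m.name}\t{m.compartment}\t{1 if m.boundary else 0}")
    lines.append("# reactions")
    for r in model.reactions:
        left = [(mid, -c) for (mid, rid), c in model.stoichiometry.items()
                if rid == r.id and c < 0]
        right = [(mid, c) for (mid, rid), c in model.stoichiometry.items()
                 if rid == r.id and c > 0]
        left.sort()
        right.sort()
        arrow = "<=>" if r.reversible else "->"
        formula = f"{_format_side(left)} {arrow} {_format_side(right)}".strip()
        obj = 1 if r.id == model.objective_reaction else 0
        lines.append(
            f"{r.id}\t{r.name}\t{_fmt(r.lower_bound)}\t{_fmt(r.upper_bound)}"
            f"\t{obj}\t{formula}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def read_sbml(path) -> MetabolicModel:
    """Read an SBML Level 3 model carrying FBC bounds and objective.

    Boundary-condition species are kept in the metabolite list (flagged) but
    excluded from the steady-state rows of ``S``.  Bounds beyond ±1000 are
    clamped with a warning.  A missing FBC objective is a hard error.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise InputError(f"cannot read SBML file {path}")
    sbml_model = doc.getModel()
    mplug = sbml_model.getPlugin("fbc")
    if mplug is None:
        raise InputError(
            f"model {sbml_model.getId()!r} in {path} lacks the FBC package"
        )
    objective = mplug.getActiveObjective()
    if objective is None and mplug.getNumObjectives() > 0:
        objective = mplug.getObjective(0)
    if objective is None or objective.getNumFluxObjectives() == 0:
        raise InputError(
            f"model {sbml_model.getId()!r} in {path} has no FBC objective"
        )
    obj_rid = objective.getFluxObjective(0).getReaction()
    sense = "minimize" if "min" in str(objective.getType()).lower() else "maximize"

    mets = [
        Metabolite(
            s.getId(), s.getName() or "", s.getCompartment() or "c",
            bool(s.getBoundaryCondition()),
        )
        for s in (sbml_model.getSpecies(i) for i in range(sbml_model.getNumSpecies()))
    ]

    def _bound(rxn, getter, default):
        rplug = rxn.getPlugin("fbc")
        pid = getter(rplug) if rplug is not None else None
        if pid:
            p = sbml_model.getParameter(pid)
            if p is not None:
                return p.getValue()
        return default

    rxns: list[Reaction] = []
    stoich: dict[tuple[str, str], float] = {}
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rev = bool(rx.getReversible())
        lb = _bound(rx, lambda p: p.getLowerFluxBound(),
                    -BOUND_CAP if rev else 0.0)
        ub = _bound(rx, lambda p: p.getUpperFluxBound(), BOUND_CAP)
        rxns.append(Reaction(rx.getId(), rx.getName() or "", lb, ub, rev))
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            key = (sr.getSpecies(), rx.getId())
            stoich[key] = stoich.get(key, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            key = (sr.getSpecies(), rx.getId())
            stoich[key] = stoich.get(key, 0.0) + sr.getStoichiometry()

    model = MetabolicModel(
        model_id=sbml_model.getId() or str(path),
        metabolites=mets, reactions=rxns, stoichiometry=stoich,
        objective_reaction=obj_rid, objective_sense=sense,
    )
    clamp_bounds(model)
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML Level 3 Version 1 with FBC v2."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(re.sub(r"[^A-Za-z0-9_]", "_", model.model_id) or "model")
    dplug = sm.getPlugin("fbc")
    dplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites} | {"c"}):
        c = sm.createCompartment()
        c.setId(comp_id)
        c.setConstant(True)
        c.setSize(1.0)

    for m in model.metabolites:
        s = sm.createSpecies()
        s.setId(m.id)
        if m.name:
            s.setName(m.name)
        s.setCompartment(m.compartment)
        s.setBoundaryCondition(m.boundary)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
        s.setInitialConcentration(0.0)

    def _param(pid: str, value: float) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        return pid

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        if r.name:
            rx.setName(r.name)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_param(f"{r.id}_lb", r.lower_bound))
        rplug.setUpperFluxBound(_param(f"{r.id}_ub", r.upper_bound))
        for (mid, rid), coef in model.stoichiometry.items():
            if rid != r.id or coef == 0.0:
                continue
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(mid)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)

    obj = dplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize" if model.objective_sense == "maximize" else "minimize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_reaction)
    fo.setCoefficient(1.0)
    dplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise InputError(f"cannot write SBML to {path}")
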
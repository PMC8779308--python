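"""Constraint-ladder study driver.

Experimental constraints are typically integrated step-wise: none (nc), then
medium composition (med), then measured uptake/secretion rates (met), then
proteome-absence data (pro).  ``run_ladder_study`` applies the constraint
sets cumulatively, rung by rung, and reports per rung the solution-space
size measures: variable-reaction counts at two width thresholds, sensitive
and robust counts from the perturbation study, the directionality-reversal
percentage, and the flux-module partition.

Rungs stay comparable yet independent: each rung's perturbation seed is
derived deterministically from the study seed and the rung index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .diagnostics import ModulePartition, partition_modules
from .errors import FluxpertError
from .lp_core import FVAResult, classify_variable, run_fva, solve_fba
from .model_core import (
    ConstraintSet,
    MetabolicModel,
    apply_constraints,
    fix_objective_flux,
    read_constraints_tsv,
)
from .perturb import (
    PerturbationConfig,
    SensitivityReport,
    classify_sensitivity,
    run_perturbation_study,
)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass
class StudyConfig:
    """One ladder study: a model, ordered constraint rungs, and parameters."""

    model: MetabolicModel
    #: constraint set per rung, applied cumulatively; first may be empty (nc)
    rungs: list[ConstraintSet]
    rung_names: list[str] | None = None
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    #: objective value to fix before FVA/perturbation; None = each rung's optimum
    fix_objective: float | None = None
    theta_coarse: float = 1e-3

    def __post_init__(self) -> None:
        if not self.rungs:
            raise FluxpertError("ladder needs at least one rung")
        if self.rung_names is None:
            self.rung_names = [f"rung{i}" for i in range(len(self.rungs))]
        if len(self.rung_names) != len(self.rungs):
            raise FluxpertError("rung_names length mismatch")

    @classmethod
    def from_paths(cls, model, constraint_paths, **kw) -> "StudyConfig":
        rungs = [read_constraints_tsv(p) for p in constraint_paths]
        names = kw.pop("rung_names", None) or [
            __import__("pathlib").Path(p).stem for p in constraint_paths
        ]
        return cls(model=model, rungs=rungs, rung_names=names, **kw)


@dataclass
class RungResult:
    name: str
    failed: bool
    error: str = ""
    n_variable_fine: int = 0       # θ = perturbation.theta_var (default 1e-6)
    n_variable_coarse: int = 0     # θ = theta_coarse (default 1e-3)
    n_sensitive: int = 0
    n_robust: int = 0
    reversal_percentage: float = 0.0
    module_sizes: list[int] = field(default_factory=list)
    fva: FVAResult | None = None
    sensitivity: SensitivityReport | None = None
    partition: ModulePartition | None = None


@dataclass
class LadderSummary:
    rungs: list[RungResult]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rung": r.name,
                    "failed": int(r.failed),
                    "n_variable": r.n_variable_fine,
                    "n_variable_coarse": r.n_variable_coarse,
                    "n_sensitive": r.n_sensitive,
                    "n_robust": r.n_robust,
                    "reversal_pct": r.reversal_percentage,
                    "n_modules": len(r.module_sizes),
                    "module_sizes": ",".join(map(str, r.module_sizes)),
                }
                for r in self.rungs
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _child_seed(seed: int | None, rung_index: int) -> int | None:
    if seed is None:
        return None
    return (seed * 1000 + rung_index) % _SEED_MOD


def run_ladder_study(cfg: StudyConfig, out_dir=None) -> LadderSummary:
    """Run the full analysis on every rung of the constraint ladder.

    An infeasible rung is marked failed and the study continues.  When
    ``out_dir`` is given, per-rung FVA and sensitivity TSVs plus the
    combined summary are written there; every summary number is re-derivable
    from the per-rung tables.
    """
    import dataclasses

    results: list[RungResult] = []
    cumulative = cfg.model
    for i, (name, cs) in enumerate(zip(cfg.rung_names, cfg.rungs)):
        try:
            cumulative = apply_constraints(cumulative, cs)
            model = cumulative
            if cfg.fix_objective is not None:
                model = fix_objective_flux(model, cfg.fix_objective)
            else:
                obj = model.reaction(model.objective_reaction)
                if obj.lower_bound != obj.upper_bound:
                    ref = solve_fba(model)
                    if ref.solver_status != "optimal":
                        raise FluxpertError(
                            f"rung {name!r} unsolvable: {ref.solver_status}"
                        )
                    model = fix_objective_flux(model, ref.objective_value)
            pcfg = dataclasses.replace(
                cfg.perturbation,
                seed=_child_seed(cfg.perturbation.seed, i),
            )
            fva = run_fva(model, gamma=pcfg.gamma, theta_var=pcfg.theta_var)
            classes_fine = classify_variable(fva, pcfg.theta_var)
            classes_coarse = classify_variable(fva, cfg.theta_coarse)
            reference = solve_fba(model)
            samples = run_perturbation_study(model, fva, pcfg)
            report = classify_sensitivity(reference, samples, fva, pcfg)
            part = partition_modules(model, fva, pcfg.theta_var)
            rr = RungResult(
                name=name, failed=False,
                n_variable_fine=sum(
                    1 for c in classes_fine.values() if c == "variable"),
                n_variable_coarse=sum(
                    1 for c in classes_coarse.values() if c == "variable"),
                n_sensitive=report.n_sensitive,
                n_robust=report.n_robust,
                reversal_percentage=report.reversal_percentage,
                module_sizes=part.sizes,
                fva=fva, sensitivity=report, partition=part,
            )
        except FluxpertError as exc:
            logger.warning("rung %s failed: %s", name, exc)
            rr = RungResult(name=name, failed=True, error=str(exc))
        results.append(rr)

    summary = LadderSummary(results)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rr in results:
            if rr.failed:
                continue
            rr.fva.to_tsv(out / f"{rr.name}_fva.tsv")
            rr.sensitivity.to_tsv(out / f"{rr.name}_sensitivity.tsv")
            (out / f"{rr.name}_modules.txt").write_text(rr.partition.to_lines())
        summary.to_tsv(out / "ladder_summary.tsv")
    return summary
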
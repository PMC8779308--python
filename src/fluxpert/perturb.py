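"""Random-perturbation inspection of the FBA solution space.

The procedure: with the objective flux fixed, determine every *variable*
reaction (FVA interval width > θ), fix each one in turn at k uniform random
values inside its own FVA interval, and re-solve.  Each re-solution is a
different member of the alternate-optima face.  A reaction is *sensitive*
if at least one perturbation moves its flux by more than δ (default 5%) of
its reference value (absolute threshold 1e-6 when the reference flux is
zero), and *robust* if it is variable but never responds.  Sensitive counts,
response intervals and directionality reversals together measure how large —
and how biologically consequential — the solution space is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleModelError, InputError
from .lp_core import (
    DEFAULT_THETA,
    FluxDistribution,
    FVAResult,
    classify_variable,
    run_fva,
    solve_fba,
)
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass
class PerturbationConfig:
    """Tunable parameters of a perturbation study.

    k:              samples per variable reaction.
    delta:          relative response threshold (0.05 = ±5%).
    zero_threshold: absolute response threshold when the reference flux is 0.
    theta_var:      FVA width above which a reaction counts as variable.
    gamma:          optimality fraction of the underlying FVA.
    mode:           "fba" re-solves one FBA per sample; "fva" re-runs FVA and
                    takes interval midpoints as the sample distribution.
    include_self:   count a reaction's own fixing toward its sensitivity.
    """

    k: int = 10
    delta: float = 0.05
    zero_threshold: float = 1e-6
    theta_var: float = DEFAULT_THETA
    gamma: float = 1.0
    mode: str = "fba"
    seed: int | None = None
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError(f"k must be >= 1, got {self.k}")
        if not (0.0 < self.delta < 1.0):
            raise InputError(f"delta must be in (0, 1), got {self.delta}")
        if self.zero_threshold <= 0 or self.theta_var <= 0:
            raise InputError("thresholds must be positive")
        if self.mode not in ("fba", "fva"):
            raise InputError(f"mode must be 'fba' or 'fva', got {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "k": self.k, "delta": self.delta,
            "zero_threshold": self.zero_threshold,
            "theta_var": self.theta_var, "gamma": self.gamma,
            "mode": self.mode, "seed": self.seed,
            "include_self": self.include_self,
        }


@dataclass
class PerturbationSample:
    """One random fixing of one reaction and the re-solved distribution."""

    perturbed_reaction: str
    fixed_value: float
    distribution: FluxDistribution | None
    status: str


@dataclass
class ReactionSensitivity:
    class_: str                  # sensitive | robust | stable | undetermined
    ref_flux: float
    fva_min: float
    fva_max: float
    response_count: int = 0
    responded_min: float = np.nan
    responded_max: float = np.nan
    reversal_count: int = 0


@dataclass
class SensitivityReport:
    """Per-reaction sensitivity classes and study-level totals."""

    reference: FluxDistribution
    rows: dict[str, ReactionSensitivity]
    n_variable: int
    n_sensitive: int
    n_robust: int
    n_failed_samples: int
    config: PerturbationConfig | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def sensitive_reactions(self) -> list[str]:
        return [r for r, s in self.rows.items() if s.class_ == "sensitive"]

    @property
    def reversal_percentage(self) -> float:
        """Percent of sensitive reactions that reversed direction at least once."""
        sens = self.sensitive_reactions
        if not sens:
            return 0.0
        n_rev = sum(1 for r in sens if self.rows[r].reversal_count > 0)
        return 100.0 * n_rev / len(sens)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "reaction_id": rid,
                    "class": s.class_,
                    "ref_flux": s.ref_flux,
                    "fva_min": s.fva_min,
                    "fva_max": s.fva_max,
                    "response_count": s.response_count,
                    "responded_min": s.responded_min,
                    "responded_max": s.responded_max,
                    "reversal_count": s.reversal_count,
                }
                for rid, s in self.rows.items()
            ]
        )

    def to_tsv_string(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False, float_format="%.10g")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_tsv_string())

    def metadata_json(self) -> str:
        meta = dict(self.metadata)
        if self.config is not None:
            meta["config"] = self.config.to_dict()
        meta.update(
            n_variable=self.n_variable, n_sensitive=self.n_sensitive,
            n_robust=self.n_robust, n_failed_samples=self.n_failed_samples,
            reversal_percentage=self.reversal_percentage,
        )
        return json.dumps(meta, indent=2, sort_keys=True)


def draw_fix_values(
    interval: tuple[float, float], k: int, rng: np.random.Generator
) -> list[float]:
    """k independent uniform draws inside ``interval`` (reproducible via rng).

    A degenerate interval (width ≤ 0) yields k copies of its lower endpoint
    with a warning — nothing to randomize over.
    """
    lo, hi = interval
    if hi - lo <= 0:
        logger.warning("degenerate interval (%g, %g); returning %d copies", lo, hi, k)
        return [float(lo)] * k
    return [float(v) for v in rng.uniform(lo, hi, size=k)]


def _fix_reaction(model: MetabolicModel, rid: str, value: float) -> MetabolicModel:
    out = model.copy()
    r = out.reaction(rid)
    r.lower_bound = r.upper_bound = value
    return out


def _solve_sample(model: MetabolicModel, cfg: PerturbationConfig):
    """Returns (distribution or None, status) for one perturbed model."""
    if cfg.mode == "fba":
        dist = solve_fba(model)
        if dist.solver_status != "optimal":
            return None, dist.solver_status
        return dist, "optimal"
    try:
        fva = run_fva(model, gamma=cfg.gamma, theta_var=cfg.theta_var)
    except InfeasibleModelError as exc:
        return None, exc.status
    if fva.n_failed > 0:
        return None, "numeric_failure"
    mid = {rid: 0.5 * (iv.minimum + iv.maximum) for rid, iv in fva.intervals.items()}
    return FluxDistribution(mid, fva.objective_value, "optimal"), "optimal"


def run_perturbation_study(
    model: MetabolicModel, fva: FVAResult, cfg: PerturbationConfig
) -> list[PerturbationSample]:
    """Perturb every variable reaction k times and collect the re-solutions.

    The model's objective must already be fixed (lb = ub).  Infeasible or
    numerically failed samples are retained with their status — they are
    edge-of-feasibility signal, not noise to retry.
    """
    obj = model.reaction(model.objective_reaction)
    if obj.lower_bound != obj.upper_bound:
        raise InputError(
            "perturbation requires the objective flux fixed (lb = ub); "
            f"got [{obj.lower_bound}, {obj.upper_bound}]"
        )
    var_class = classify_variable(fva, cfg.theta_var)
    variable = [rid for rid in model.reaction_ids
                if var_class.get(rid) == "variable"]
    if not variable:
        logger.warning("no variable reactions at theta=%g: empty study", cfg.theta_var)
        return []
    rng = np.random.default_rng(cfg.seed)
    samples: list[PerturbationSample] = []
    for rid in variable:
        iv = fva[rid]
        for value in draw_fix_values((iv.minimum, iv.maximum), cfg.k, rng):
            dist, status = _solve_sample(_fix_reaction(model, rid, value), cfg)
            samples.append(PerturbationSample(rid, value, dist, status))
    return samples


def _responds(v_ref: float, v_s: float, cfg: PerturbationConfig) -> bool:
    if abs(v_ref) > cfg.zero_threshold:
        return abs(v_s - v_ref) > cfg.delta * abs(v_ref)
    return abs(v_s - v_ref) > cfg.zero_threshold


def classify_sensitivity(
    reference: FluxDistribution,
    samples: list[PerturbationSample],
    fva: FVAResult,
    cfg: PerturbationConfig,
) -> SensitivityReport:
    """Partition reactions into sensitive / robust / stable / undetermined.

    A variable reaction is sensitive iff it responds (moves beyond δ·|ref|,
    or beyond the absolute zero-threshold for zero reference flux) in at
    least one counted optimal sample; self-fixings count iff
    ``cfg.include_self``.  Response intervals and reversal counts are
    computed over responding / optimal samples respectively.
    """
    ref_ids = set(reference.fluxes)
    for s in samples:
        if s.distribution is not None and set(s.distribution.fluxes) != ref_ids:
            raise InputError(
                f"sample perturbing {s.perturbed_reaction!r} comes from a "
                "different model topology than the reference"
            )
    var_class = classify_variable(fva, cfg.theta_var)
    reversals = detect_reversals(reference, samples)
    rows: dict[str, ReactionSensitivity] = {}
    n_sensitive = n_robust = n_variable = 0
    for rid in reference.fluxes:
        iv = fva.intervals.get(rid)
        row = ReactionSensitivity(
            class_=var_class.get(rid, "undetermined"),
            ref_flux=reference[rid],
            fva_min=iv.minimum if iv is not None else np.nan,
            fva_max=iv.maximum if iv is not None else np.nan,
            reversal_count=reversals.get(rid, 0),
        )
        if row.class_ == "variable":
            n_variable += 1
            responded: list[float] = []
            for s in samples:
                if s.status != "optimal" or s.distribution is None:
                    continue
                if s.perturbed_reaction == rid and not cfg.include_self:
                    continue
                v_s = s.distribution[rid]
                if _responds(row.ref_flux, v_s, cfg):
                    responded.append(v_s)
            row.response_count = len(responded)
            if responded:
                row.class_ = "sensitive"
                row.responded_min = min(responded)
                row.responded_max = max(responded)
                n_sensitive += 1
            else:
                row.class_ = "robust"
                n_robust += 1
        rows[rid] = row
    n_failed = sum(1 for s in samples if s.status != "optimal")
    return SensitivityReport(
        reference=reference, rows=rows,
        n_variable=n_variable, n_sensitive=n_sensitive, n_robust=n_robust,
        n_failed_samples=n_failed, config=cfg,
        metadata={"n_samples": len(samples), "gamma": fva.gamma},
    )


def detect_reversals(
    reference: FluxDistribution,
    samples: list[PerturbationSample],
    magnitude_eps: float = 1e-6,
) -> dict[str, int]:
    """Count, per reaction, optimal samples where the flux changed sign.

    A reversal needs a strict sign flip with both magnitudes above
    ``magnitude_eps``; a flux at (numerical) zero is signless.
    """
    counts: dict[str, int] = {}
    for s in samples:
        if s.status != "optimal" or s.distribution is None:
            continue
        for rid, v_ref in reference.fluxes.items():
            v_s = s.distribution[rid]
            if (
                abs(v_ref) > magnitude_eps
                and abs(v_s) > magnitude_eps
                and np.sign(v_ref) * np.sign(v_s) < 0
            ):
                counts[rid] = counts.get(rid, 0) + 1
    return counts


def bin_response_positions(
    reference: FluxDistribution,
    samples: list[PerturbationSample],
    fva: FVAResult,
    cfg: PerturbationConfig,
    nbins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled histogram of where sensitive reactions' fluxes sit inside
    their FVA intervals.

    Every flux value taken by a sensitive reaction (interval width > 0)
    across the optimal samples is mapped to its normalized position
    (v − min)/(max − min), clipped into [0, 1] after a 1e-9 tolerance, and
    counted over ``nbins`` equal-width bins (right-open except the last).
    Returns ``(counts, bin_edges)``; counts sum to the number of pooled
    values.
    """
    report = classify_sensitivity(reference, samples, fva, cfg)
    positions: list[float] = []
    for rid in report.sensitive_reactions:
        iv = fva[rid]
        if not iv.ok or iv.width <= 0:
            continue
        for s in samples:
            if s.status != "optimal" or s.distribution is None:
                continue
            pos = (s.distribution[rid] - iv.minimum) / iv.width
            if -1e-9 <= pos <= 1.0 + 1e-9:
                positions.append(float(np.clip(pos, 0.0, 1.0)))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts = np.zeros(nbins, dtype=int)
    for pos in positions:
        counts[min(int(pos * nbins), nbins - 1)] += 1
    return counts, edges
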
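"""Flux partitioning at metabolic branching points across alternate optima.

FVA gives per-reaction flux ranges but says nothing about permissible
*ratios* between fluxes.  At a branching metabolite (pyruvate deciding
between homolactic and mixed-acid fermentation is the canonical case), the
biologically meaningful quantity is which fraction of the metabolite's
consumption each branch carries in each sampled optimal distribution.

A reaction's contribution in a sample is its consumption of the focus
metabolite, max(0, −s·v), with s the stoichiometric coefficient: the |s|
weighting makes fractions measure metabolite fate rather than reaction
activity.  Production (negative contribution) is clipped to zero and
logged — only the consumption split is analyzed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .errors import InputError
from .lp_core import FluxDistribution, FVAResult
from .model_core import MetabolicModel
from .perturb import PerturbationSample

logger = logging.getLogger(__name__)

_ZERO_TOTAL = 1e-9


@dataclass
class BranchSpec:
    """A focus metabolite and the reactions competing for it."""

    focus_metabolite: str
    branch_reactions: list[str]
    #: reaction id -> phenotype label; several reactions may share a label
    labels: dict[str, str] = field(default_factory=dict)

    def label_of(self, rid: str) -> str:
        return self.labels.get(rid, rid)

    @property
    def label_order(self) -> list[str]:
        seen: list[str] = []
        for rid in self.branch_reactions:
            lab = self.label_of(rid)
            if lab not in seen:
                seen.append(lab)
        return seen

    def validate(self, model: MetabolicModel) -> None:
        for rid in self.branch_reactions:
            if model.stoichiometry.get((self.focus_metabolite, rid), 0.0) == 0.0:
                raise InputError(
                    f"branch reaction {rid!r} has zero stoichiometry for "
                    f"{self.focus_metabolite!r}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "focus_metabolite": self.focus_metabolite,
                "branch_reactions": self.branch_reactions,
                "labels": self.labels,
            },
            indent=2,
        )


@dataclass
class BranchSample:
    perturbed_reaction: str | None
    fixed_value: float | None
    fractions: dict[str, float] | None     # label -> fraction; None = undefined


@dataclass
class BranchReport:
    """Per-sample branch fractions plus the reference split and ranges."""

    spec: BranchSpec
    reference_fractions: dict[str, float] | None
    samples: list[BranchSample]

    def summary(self) -> dict[str, tuple[float, float]]:
        """(min, max) fraction per label over samples with defined fractions."""
        out: dict[str, tuple[float, float]] = {}
        for lab in self.spec.label_order:
            vals = [s.fractions[lab] for s in self.samples if s.fractions is not None]
            if vals:
                out[lab] = (min(vals), max(vals))
        return out

    def to_frame(self, one_per_reaction: bool = False):
        import pandas as pd

        rows = []
        seen: set[str] = set()
        for s in self.samples:
            if one_per_reaction:
                if s.perturbed_reaction in seen:
                    continue
                seen.add(s.perturbed_reaction)
            row = {
                "perturbed_reaction": s.perturbed_reaction,
                "fixed_value": s.fixed_value,
            }
            for lab in self.spec.label_order:
                row[lab] = s.fractions[lab] if s.fractions is not None else float("nan")
            row["defined"] = int(s.fractions is not None)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path, one_per_reaction: bool = False) -> None:
        self.to_frame(one_per_reaction).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def branch_from_metabolite(
    model: MetabolicModel,
    metabolite_id: str,
    reference: FluxDistribution,
    fva: FVAResult | None = None,
    consumption_tol: float = 1e-9,
) -> BranchSpec:
    """Propose the consuming reactions of a metabolite as a branch spec.

    Included are all reactions with positive signed consumption −s·v in the
    reference distribution, plus (when an FVA result is supplied) reactions
    with negative stoichiometry and a non-degenerate FVA interval — they may
    consume in other members of the optimal face even if idle in the
    reference.  Fewer than two candidates is an error: specify the branch
    manually.
    """
    model.metabolite(metabolite_id)
    candidates: set[str] = set()
    for (mid, rid), s in model.stoichiometry.items():
        if mid != metabolite_id or s == 0.0:
            continue
        if rid in reference.fluxes and -s * reference[rid] > consumption_tol:
            candidates.add(rid)
        elif s < 0 and fva is not None and rid in fva.intervals:
            iv = fva[rid]
            if iv.ok and iv.width > consumption_tol:
                candidates.add(rid)
    if len(candidates) < 2:
        raise InputError(
            f"metabolite {metabolite_id!r} has {len(candidates)} consuming "
            "candidate(s); a branch needs at least 2 — specify it manually"
        )
    return BranchSpec(metabolite_id, sorted(candidates))


def _fractions(
    spec: BranchSpec, model: MetabolicModel, dist: FluxDistribution
) -> dict[str, float] | None:
    contrib: dict[str, float] = {lab: 0.0 for lab in spec.label_order}
    for rid in spec.branch_reactions:
        s = model.stoichiometry[(spec.focus_metabolite, rid)]
        c = -s * dist[rid]
        if c < -_ZERO_TOTAL:
            logger.info(
                "branch reaction %s produces %s in this sample; clipped to 0",
                rid, spec.focus_metabolite,
            )
        contrib[spec.label_of(rid)] += max(0.0, c)
    total = sum(contrib.values())
    if total <= _ZERO_TOTAL:
        logger.warning(
            "total consumption of %s is ~0; fractions undefined",
            spec.focus_metabolite,
        )
        return None
    return {lab: c / total for lab, c in contrib.items()}


def analyze_branch(
    spec: BranchSpec,
    samples: list[PerturbationSample],
    reference: FluxDistribution,
    model: MetabolicModel,
) -> BranchReport:
    """Branch fractions in the reference and in every perturbation sample.

    Defined fractions sum to 1 per sample; a sample whose total consumption
    of the focus metabolite is ~0 (or that failed to solve) gets undefined
    fractions.
    """
    spec.validate(model)
    ref_fracs = _fractions(spec, model, reference)
    out: list[BranchSample] = []
    for s in samples:
        if s.status != "optimal" or s.distribution is None:
            out.append(BranchSample(s.perturbed_reaction, s.fixed_value, None))
            continue
        out.append(
            BranchSample(
                s.perturbed_reaction, s.fixed_value,
                _fractions(spec, model, s.distribution),
            )
        )
    return BranchReport(spec=spec, reference_fractions=ref_fracs, samples=out)
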
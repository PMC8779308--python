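"""Shared fixtures: synthetic networks and pre-run perturbation studies."""

from dataclasses import dataclass

import pytest

import fluxpert as fp


@pytest.fixture(scope="session")
def chain():
    return fp.make_chain(2, 10.0)


@pytest.fixture(scope="session")
def diamond():
    return fp.make_diamond(2, 10.0)


@pytest.fixture(scope="session")
def diamond3():
    return fp.make_diamond(3, 6.0)


@pytest.fixture(scope="session")
def double_diamond():
    return fp.make_double_diamond(10.0)


@pytest.fixture(scope="session")
def atp_toy():
    return fp.make_atp_toy(10.0, 1.0, 2.0)


@pytest.fixture(scope="session", params=["chain", "diamond", "diamond3",
                                         "double_diamond", "atp_toy"])
def any_bundle(request):
    return request.getfixturevalue(request.param)


def fixed_face(bundle, gamma=1.0):
    """Objective fixed at the bundle's optimum + FVA over that face."""
    model = fp.fix_objective_flux(bundle.model, bundle.optimum)
    return model, fp.run_fva(model, gamma=gamma)


@dataclass
class Study:
    model: object
    fva: object
    cfg: fp.PerturbationConfig
    reference: fp.FluxDistribution
    samples: list
    report: fp.SensitivityReport


def run_study(bundle, seed=42, **cfg_kw) -> Study:
    model, fva = fixed_face(bundle)
    cfg = fp.PerturbationConfig(seed=seed, **cfg_kw)
    reference = fp.solve_fba(model)
    samples = fp.run_perturbation_study(model, fva, cfg)
    report = fp.classify_sensitivity(reference, samples, fva, cfg)
    return Study(model, fva, cfg, reference, samples, report)


@pytest.fixture(scope="session")
def diamond_study(diamond):
    return run_study(diamond, seed=42)


def make_reversible_toy() -> fp.MetabolicModel:
    """A ⇄ B via a reversible route plus an antiparallel-capable one.

    With uptake pinned at 10 and the alternative route allowed up to 20,
    the net flux of the reversible reaction spans [-10, 10]: perturbations
    can flip its direction.
    """
    model = fp.MetabolicModel(
        model_id="reversible_toy",
        metabolites=[fp.Metabolite("A"), fp.Metabolite("B")],
        reactions=[
            fp.Reaction("R_in", "", 0.0, 10.0),
            fp.Reaction("R_rev", "", -1000.0, 1000.0, reversible=True),
            fp.Reaction("R_alt", "", 0.0, 20.0),
            fp.Reaction("R_out", "", 0.0, 1000.0),
        ],
        stoichiometry={
            ("A", "R_in"): 1.0,
            ("A", "R_rev"): -1.0, ("B", "R_rev"): 1.0,
            ("A", "R_alt"): -1.0, ("B", "R_alt"): 1.0,
            ("B", "R_out"): -1.0,
        },
        objective_reaction="R_out",
    )
    model.validate()
    return model
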
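"""Perturbation sampling, sensitivity classification and reversal counts."""

import numpy as np
import pytest
from scipy import stats

import fluxpert as fp
from fluxpert.errors import InputError
from fluxpert.lp_core import FVAInterval, FVAResult

from conftest import fixed_face, make_reversible_toy, run_study


class TestDrawFixValues:
    def test_deterministic_and_in_range(self):
        vals1 = fp.draw_fix_values((0.0, 10.0), 10, np.random.default_rng(7))
        vals2 = fp.draw_fix_values((0.0, 10.0), 10, np.random.default_rng(7))
        assert vals1 == vals2
        assert len(vals1) == 10
        assert all(0.0 <= v <= 10.0 for v in vals1)

    def test_degenerate_interval_returns_copies(self):
        vals = fp.draw_fix_values((5.0, 5.0), 10, np.random.default_rng(0))
        assert vals == [5.0] * 10

    def test_uniformity_by_kolmogorov_smirnov(self):
        vals = fp.draw_fix_values((0.0, 1.0), 10_000, np.random.default_rng(0))
        assert stats.kstest(vals, "uniform").pvalue > 0.01


class TestRunStudy:
    def test_diamond_produces_k_samples_per_variable_reaction(self, diamond_study):
        s = diamond_study
        assert len(s.samples) == 40
        assert all(x.status == "optimal" for x in s.samples)
        assert {x.perturbed_reaction for x in s.samples} == \
            {"R_ab", "R_ac", "R_bd", "R_cd"}

    def test_every_optimal_sample_conserves_the_fixed_objective(self, diamond_study):
        for x in diamond_study.samples:
            assert x.distribution.objective_value == pytest.approx(10.0, abs=1e-6)
            assert x.distribution["R_out"] == pytest.approx(10.0, abs=1e-6)

    def test_perturbed_flux_equals_its_fixed_value(self, diamond_study):
        for x in diamond_study.samples:
            assert x.distribution[x.perturbed_reaction] == \
                pytest.approx(x.fixed_value, abs=1e-9)

    def test_fixing_one_path_reaction_has_unique_completion(self, diamond):
        model, _ = fixed_face(diamond)
        r = model.reaction("R_ab")
        r.lower_bound = r.upper_bound = 2.5
        dist = fp.solve_fba(model)
        assert dist["R_bd"] == pytest.approx(2.5, abs=1e-9)
        assert dist["R_ac"] == pytest.approx(7.5, abs=1e-9)
        assert dist["R_cd"] == pytest.approx(7.5, abs=1e-9)

    def test_chain_study_is_empty(self, chain):
        model, fva = fixed_face(chain)
        samples = fp.run_perturbation_study(
            model, fva, fp.PerturbationConfig(seed=1))
        assert samples == []

    def test_unfixed_objective_is_rejected(self, diamond):
        fva = fp.run_fva(fp.fix_objective_flux(diamond.model, 10.0))
        with pytest.raises(InputError, match="fixed"):
            fp.run_perturbation_study(
                diamond.model, fva, fp.PerturbationConfig(seed=1))

    def test_fva_mode_midpoint_distributions_conserve_objective(self, diamond):
        s = run_study(diamond, seed=3, k=2, mode="fva")
        assert all(x.status == "optimal" for x in s.samples)
        for x in s.samples:
            assert x.distribution.objective_value == pytest.approx(10.0, abs=1e-6)


class TestClassifySensitivity:
    def test_diamond_all_path_reactions_sensitive(self, diamond_study):
        rep = diamond_study.report
        assert rep.n_variable == 4
        assert rep.n_sensitive == 4
        assert rep.n_robust == 0
        assert rep.rows["R_in"].class_ == "stable"
        assert rep.rows["R_out"].class_ == "stable"

    def test_fixing_a_path_reaction_at_zero_moves_all_four(self, diamond):
        model, fva = fixed_face(diamond)
        ref = fp.solve_fba(model)
        fixed = model.copy()
        r = fixed.reaction("R_ab")
        r.lower_bound = r.upper_bound = 0.0
        dist = fp.solve_fba(fixed)
        cfg = fp.PerturbationConfig(seed=0)
        sample = fp.PerturbationSample("R_ab", 0.0, dist, "optimal")
        rep = fp.classify_sensitivity(ref, [sample], fva, cfg)
        for rid in ("R_ab", "R_ac", "R_bd", "R_cd"):
            assert rep.rows[rid].class_ == "sensitive"

    def test_zero_reference_uses_absolute_threshold(self):
        fva = FVAResult(
            gamma=1.0, objective_value=0.0,
            intervals={"R1": FVAInterval(0.0, 1.0, "optimal", "optimal")},
        )
        ref = fp.FluxDistribution({"R1": 0.0}, 0.0, "optimal")
        cfg = fp.PerturbationConfig(seed=0)

        def sample(v):
            return fp.PerturbationSample(
                "R1", v, fp.FluxDistribution({"R1": v}, 0.0, "optimal"), "optimal")

        below = fp.classify_sensitivity(ref, [sample(5e-7)], fva, cfg)
        assert below.rows["R1"].class_ == "robust"
        above = fp.classify_sensitivity(ref, [sample(2e-6)], fva, cfg)
        assert above.rows["R1"].class_ == "sensitive"

    def test_responded_intervals_contained_in_fva_intervals(self, diamond_study):
        s = diamond_study
        for rid in s.report.sensitive_reactions:
            row = s.report.rows[rid]
            assert row.responded_min >= s.fva[rid].minimum - 1e-6
            assert row.responded_max <= s.fva[rid].maximum + 1e-6

    def test_include_self_false_drops_self_samples_from_counts(self, diamond):
        with_self = run_study(diamond, seed=5)
        without = run_study(diamond, seed=5, include_self=False)
        for rid in with_self.report.sensitive_reactions:
            assert without.report.rows[rid].response_count <= \
                with_self.report.rows[rid].response_count
        assert all(without.report.rows[r].response_count <= 30
                   for r in without.report.rows)

    def test_topology_mismatch_is_a_hard_error(self, diamond_study):
        alien = fp.PerturbationSample(
            "R_x", 1.0, fp.FluxDistribution({"R_x": 1.0}, 0.0, "optimal"),
            "optimal")
        with pytest.raises(InputError, match="topology"):
            fp.classify_sensitivity(
                diamond_study.reference, [alien], diamond_study.fva,
                diamond_study.cfg)

    def test_failed_samples_counted_but_excluded(self, diamond_study):
        s = diamond_study
        bad = fp.PerturbationSample("R_ab", 99.0, None, "infeasible")
        rep = fp.classify_sensitivity(
            s.reference, list(s.samples) + [bad], s.fva, s.cfg)
        assert rep.n_failed_samples == 1
        assert rep.n_sensitive == s.report.n_sensitive

    def test_narrow_interval_reaction_cannot_be_sensitive(self, diamond):
        # width below theta => stable, and a stable reaction never responds
        model, _ = fixed_face(diamond)
        model.reaction("R_ab").upper_bound = 6.0
        fva = fp.run_fva(model)
        s = run_study_from(model, fva, seed=9)
        for rid, row in s.report.rows.items():
            if fva[rid].width <= s.cfg.theta_var:
                assert row.class_ in ("stable", "undetermined")

    def test_tightening_ladder_never_increases_sensitive_count(self, diamond):
        counts = []
        for ub in (10.0, 6.0, 3.0):
            model, _ = fixed_face(diamond)
            model.reaction("R_ab").upper_bound = ub
            fva = fp.run_fva(model)
            counts.append(run_study_from(model, fva, seed=11).report.n_sensitive)
        assert counts == sorted(counts, reverse=True)


def run_study_from(model, fva, seed):
    from conftest import Study

    cfg = fp.PerturbationConfig(seed=seed)
    ref = fp.solve_fba(model)
    samples = fp.run_perturbation_study(model, fva, cfg)
    report = fp.classify_sensitivity(ref, samples, fva, cfg)
    return Study(model, fva, cfg, ref, samples, report)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_reports(self, diamond):
        r1 = run_study(diamond, seed=42).report
        r2 = run_study(diamond, seed=42).report
        assert r1.to_tsv_string() == r2.to_tsv_string()

    def test_different_seed_changes_values_not_classes(self, diamond):
        r1 = run_study(diamond, seed=1).report
        r2 = run_study(diamond, seed=2).report
        assert {k: v.class_ for k, v in r1.rows.items()} == \
            {k: v.class_ for k, v in r2.rows.items()}


class TestReversals:
    def test_sign_flip_counts_as_reversal(self):
        ref = fp.FluxDistribution({"R1": 2.0}, 0.0, "optimal")
        flip = fp.PerturbationSample(
            "R1", -3.0, fp.FluxDistribution({"R1": -3.0}, 0.0, "optimal"),
            "optimal")
        assert fp.detect_reversals(ref, [flip]) == {"R1": 1}

    def test_zero_flux_is_signless(self):
        ref = fp.FluxDistribution({"R1": 2.0}, 0.0, "optimal")
        zero = fp.PerturbationSample(
            "R1", 0.0, fp.FluxDistribution({"R1": 0.0}, 0.0, "optimal"),
            "optimal")
        assert fp.detect_reversals(ref, [zero]) == {}

    def test_reversible_route_flips_exactly_once_per_sample(self):
        model = fp.fix_objective_flux(make_reversible_toy(), 10.0)
        fva = fp.run_fva(model)
        assert fva["R_rev"].minimum == pytest.approx(-10.0, abs=1e-6)
        assert fva["R_rev"].maximum == pytest.approx(10.0, abs=1e-6)
        ref = fp.solve_fba(model)
        # drive the net flux to the opposite sign of the reference
        target = -5.0 if ref["R_rev"] > 0 else 5.0
        fixed = model.copy()
        r = fixed.reaction("R_rev")
        r.lower_bound = r.upper_bound = target
        dist = fp.solve_fba(fixed)
        sample = fp.PerturbationSample("R_rev", target, dist, "optimal")
        assert fp.detect_reversals(ref, [sample])["R_rev"] == 1


class TestBinning:
    def _one_value_setup(self, v):
        fva = FVAResult(
            gamma=1.0, objective_value=0.0,
            intervals={"R1": FVAInterval(0.0, 10.0, "optimal", "optimal")},
        )
        ref = fp.FluxDistribution({"R1": 9.0}, 0.0, "optimal")
        sample = fp.PerturbationSample(
            "R1", v, fp.FluxDistribution({"R1": v}, 0.0, "optimal"), "optimal")
        cfg = fp.PerturbationConfig(seed=0)
        return fp.bin_response_positions(ref, [sample], fva, cfg, nbins=20)

    def test_midpoint_value_falls_in_bin_11_of_20(self):
        counts, _ = self._one_value_setup(5.0)
        assert counts[10] == 1 and counts.sum() == 1

    @pytest.mark.parametrize("v,bin_idx", [(0.0, 0), (10.0, 19)])
    def test_endpoint_values_fall_in_first_and_last_bin(self, v, bin_idx):
        counts, _ = self._one_value_setup(v)
        assert counts[bin_idx] == 1

    def test_histogram_total_equals_pooled_values(self, diamond_study):
        s = diamond_study
        counts, edges = fp.bin_response_positions(
            s.reference, s.samples, s.fva, s.cfg)
        # 4 sensitive reactions observed across 40 optimal samples
        assert counts.sum() == 160
        assert len(edges) == 21

    def test_pooled_histogram_is_uniform_on_the_diamond(self, diamond):
        # Fixing any path reaction at v makes the four path fluxes take
        # values {v, v, 10-v, 10-v}: the pooled histogram mirrors exactly
        # and each draw fills a folded cell 4 times.  Folding restores a
        # proper multinomial null for the chi-square test.
        s = run_study(diamond, seed=0, k=100)
        counts, _ = fp.bin_response_positions(
            s.reference, s.samples, s.fva, s.cfg)
        assert counts.sum() == 4 * 4 * 100
        folded = counts[:10] + counts[:9:-1]
        assert np.all(folded % 4 == 0)
        assert stats.chisquare(folded // 4).pvalue > 0.01
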
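"""Synthetic cohort generator: determinism, marginals, analytic oracle."""

import dataclasses

import numpy as np
import pytest

from ovatriage import (
    analytic_marginals,
    analytic_operating_points,
    classify_iota,
    default_params,
    generate_cohort,
    validate_record,
)
from ovatriage.synth import (
    MarkerModel,
    ParameterError,
    load_params,
    params_digest,
    save_params,
    validate_params,
)


class TestParams:
    def test_defaults_pass_their_own_invariants(self):
        validate_params(default_params())

    def test_analytic_prevalence_is_the_configured_value(self):
        assert analytic_marginals(default_params())["prevalence"] == 0.206

    def test_default_inconclusive_rate_in_study_band(self):
        rate = analytic_marginals(default_params())["inconclusive_rate"]
        assert 0.20 <= rate <= 0.30

    def test_site_mixture_must_reproduce_overall_prevalence(self):
        with pytest.raises(ParameterError, match="mix to 1"):
            default_params(site_rr=(2.0, 1.0))

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError, match="prevalence"):
            default_params(prevalence=1.2)

    def test_yaml_round_trip(self, tmp_path):
        params = default_params(n=50, seed=9, he4_missing_frac=0.1)
        path = tmp_path / "params.yaml"
        save_params(params, path)
        assert load_params(path) == params
        assert params_digest(load_params(path)) == params_digest(params)


class TestGeneration:
    def test_empty_cohort(self):
        assert len(generate_cohort(default_params(n=0))) == 0

    def test_same_seed_gives_identical_cohorts(self):
        params = default_params(n=300, seed=77)
        first = generate_cohort(params)
        second = generate_cohort(params)
        assert first.records == second.records
        assert first.provenance == second.provenance

    def test_different_seed_gives_different_cohort(self):
        a = generate_cohort(default_params(n=300, seed=1))
        b = generate_cohort(default_params(n=300, seed=2))
        assert a.records != b.records

    def test_every_generated_record_is_valid(self, cohort_1k):
        for record in cohort_1k:
            assert validate_record(record) == []

    def test_expert_coverage_inconclusive_only(self, cohort_1k):
        for record in cohort_1k:
            conclusive = classify_iota(record.exam).conclusive
            assert (record.expert_call is None) == conclusive

    def test_expert_coverage_all(self):
        cohort = generate_cohort(default_params(n=200, seed=5, expert_coverage="all"))
        assert all(r.expert_call is not None for r in cohort)

    def test_stage_only_on_invasive_malignant(self, cohort_1k):
        for record in cohort_1k:
            assert (record.figo_stage is not None) == (record.histology == "malignant")

    def test_marginals_recovered_within_binomial_tolerance(self):
        params = default_params(n=20000, seed=13)
        cohort = generate_cohort(params)
        marg = analytic_marginals(params)
        n = len(cohort)

        def within(observed: float, expected: float) -> bool:
            se = np.sqrt(expected * (1 - expected) / n)
            return abs(observed - expected) <= 3 * se

        prevalence = sum(r.truth_malignant for r in cohort) / n
        premeno = sum(r.menopausal == "pre" for r in cohort) / n
        inconclusive = sum(not classify_iota(r.exam).conclusive for r in cohort) / n
        assert within(prevalence, marg["prevalence"])
        assert within(premeno, marg["premenopausal_frac"])
        assert within(inconclusive, marg["inconclusive_rate"])

    def test_expert_error_model_on_inconclusive_stratum(self):
        params = default_params(n=20000, seed=29)
        cohort = generate_cohort(params)
        covered = [r for r in cohort if r.expert_call is not None]
        mal = [r for r in covered if r.truth_malignant]
        ben = [r for r in covered if not r.truth_malignant]
        sens = sum(r.expert_call == "malignant" for r in mal) / len(mal)
        spec = sum(r.expert_call == "benign" for r in ben) / len(ben)
        assert abs(sens - params.expert_sens) <= 3 * np.sqrt(0.81 * 0.19 / len(mal))
        assert abs(spec - params.expert_spec) <= 3 * np.sqrt(0.717 * 0.283 / len(ben))


class TestAnalyticOperatingPoints:
    def test_expert_strategy_decomposes_exactly(self):
        """IOTA_EXPERT = IOTA conclusive part + expert accuracy on the rest."""
        params = default_params()
        ops = analytic_operating_points(params)
        marg = analytic_marginals(params)
        iota_sens_joint = ops.loc["IOTA_ONLY", "sensitivity"] * (1 - marg["inconclusive_rate_malignant"])
        expected_sens = iota_sens_joint + marg["inconclusive_rate_malignant"] * params.expert_sens
        assert ops.loc["IOTA_EXPERT", "sensitivity"] == pytest.approx(expected_sens, abs=1e-12)

    def test_degenerate_markers_give_step_operating_points(self):
        params = default_params()
        markers = {
            cls: {
                meno: MarkerModel(ca125_mu=mm.ca125_mu, ca125_sigma=0.0,
                                  he4_mu=mm.he4_mu, he4_sigma=0.0)
                for meno, mm in per.items()
            }
            for cls, per in params.markers.items()
        }
        frozen = dataclasses.replace(params, markers=markers)
        ops = analytic_operating_points(frozen)
        assert ops.loc["ROMA_ALONE", "sensitivity"] in (0.0, 1.0)
        assert ops.loc["ROMA_ALONE", "specificity"] in (0.0, 1.0)

    def test_operating_points_are_probabilities(self):
        ops = analytic_operating_points(default_params())
        assert ((ops >= 0) & (ops <= 1)).all().all()
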
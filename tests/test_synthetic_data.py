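import math

import numpy as np
import pytest

from ddisignal import (
    RuleThresholds,
    build_table,
    default_config,
    enumerate_candidates,
    generate_reports,
    recovery_experiment,
    rule_metrics,
    scan_omega,
    summarize_recovery,
)
from ddisignal.contingency import TableBuilder, TripleCandidate
from ddisignal.synthetic_data import SynthConfig

from bruteforce import brute_cells, brute_e111, brute_metrics, brute_omega


def near_unit_acceptance_config(**overrides):
    """Dominant drug and background AE keep the >=1-drug / >=1-AE regeneration
    rate tiny, so empirical marginals stay comparable to configured values."""
    base = dict(
        n_reports=50_000,
        drug_catalog=(("Base", 0.99), ("A", 0.05), ("B", 0.05), ("Mid", 0.30)),
        ae_catalog=(("Background", 0.99, ""), ("X", 0.002, ""), ("Y", 0.05, "")),
        seed=0,
    )
    base.update(overrides)
    return SynthConfig(**base)


class TestSynthConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_reports=10, drug_catalog=(("A", 1.5),),
                        ae_catalog=(("X", 0.1, ""),), seed=0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_reports=10, drug_catalog=(("A", 0.5), ("B", 0.5)),
                        ae_catalog=(("X", 0.1, ""),),
                        injected_effects=(("A", "B", "X", -1.0),), seed=0)

    def test_sex_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SynthConfig(n_reports=10, drug_catalog=(("A", 0.5),),
                        ae_catalog=(("X", 0.1, ""),), seed=0,
                        sex_probs=(0.5, 0.4, 0.2))


class TestGenerateReports:
    def test_same_seed_identical(self):
        config = default_config(n_reports=500, seed=3)
        a, _ = generate_reports(config)
        b, _ = generate_reports(config)
        assert a == b

    def test_different_seed_differs(self):
        a, _ = generate_reports(default_config(n_reports=500, seed=3))
        b, _ = generate_reports(default_config(n_reports=500, seed=4))
        assert a != b

    def test_every_report_has_drug_and_ae(self):
        reports, _ = generate_reports(default_config(n_reports=1_000, seed=1))
        assert all(r.drugs and r.aes for r in reports)

    def test_marginal_convergence_three_sd(self):
        # with no injected effects, drugs and AEs are sampled independently,
        # so the exact post-regeneration marginal is p / (1 - P(none))
        config = near_unit_acceptance_config(seed=11)
        reports, _ = generate_reports(config)
        n = config.n_reports
        p_no_drug = math.prod(1 - p for _, p in config.drug_catalog)
        p_no_ae = math.prod(1 - p for _, p, _ in config.ae_catalog)
        for name, p in config.drug_catalog:
            observed = sum(1 for r in reports if name in r.drugs) / n
            expected = p / (1 - p_no_drug)
            tol = 3.0 * math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < tol, (name, observed, expected)
            assert abs(expected - p) < 0.01  # near-unit acceptance by design
        for name, p, _ in config.ae_catalog:
            observed = sum(1 for r in reports if name in r.aes) / n
            expected = p / (1 - p_no_ae)
            tol = 3.0 * math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < tol, (name, observed, expected)
            assert abs(expected - p) < 0.01

    def test_null_lambda_leaves_both_exposed_rate_at_baseline(self):
        config = near_unit_acceptance_config(
            seed=21, n_reports=20_000,
            injected_effects=(("A", "B", "Y", 1.0),),
        )
        reports, _ = generate_reports(config)
        both = [r for r in reports if {"A", "B"} <= r.drugs]
        rate = sum(1 for r in both if "Y" in r.aes) / len(both)
        se = math.sqrt(0.05 * 0.95 / len(both))
        assert abs(rate - 0.05) < 3 * se + 0.003

    def test_injected_n111_matches_closed_form_expectation(self):
        # lambda=20 on baseline 0.002 with exposures 0.05: per-report joint
        # probability 0.05^2 * 0.04, i.e. E[n111] = 5 at n = 50,000
        config = near_unit_acceptance_config(
            seed=31, injected_effects=(("A", "B", "X", 20.0),))
        reports, truth = generate_reports(config)
        expected = truth.effects[0]["expected_n111"]
        assert expected == pytest.approx(50_000 * 0.05 * 0.05 * 0.002 * 20.0)
        t = build_table(reports, TripleCandidate("A", "B", "X"))
        assert abs(t.n111 - expected) < 3.0 * math.sqrt(expected) + 1.0

    def test_copair_boost_raises_joint_exposure(self):
        boosted = near_unit_acceptance_config(
            seed=41, n_reports=20_000, copair_boost=(("A", "B", 10.0),))
        plain = near_unit_acceptance_config(seed=41, n_reports=20_000)
        n_boosted = sum(1 for r in generate_reports(boosted)[0] if {"A", "B"} <= r.drugs)
        n_plain = sum(1 for r in generate_reports(plain)[0] if {"A", "B"} <= r.drugs)
        assert n_boosted > 3 * max(n_plain, 1)

    def test_single_drug_effect_raises_exposed_rate(self):
        config = near_unit_acceptance_config(
            seed=51, n_reports=20_000, single_drug_effects=(("Mid", "Y", 5.0),))
        reports, _ = generate_reports(config)
        exposed = [r for r in reports if "Mid" in r.drugs]
        unexposed = [r for r in reports if "Mid" not in r.drugs]
        rate_e = sum(1 for r in exposed if "Y" in r.aes) / len(exposed)
        rate_u = sum(1 for r in unexposed if "Y" in r.aes) / len(unexposed)
        assert rate_e > 3 * rate_u

    def test_ground_truth_derivable_from_config_alone(self):
        config = near_unit_acceptance_config(
            seed=61, injected_effects=(("A", "B", "X", 20.0),))
        _, t1 = generate_reports(config)
        _, t2 = generate_reports(config.with_seed(62))
        assert t1.effects == t2.effects  # independent of the realized sample

    def test_impossible_config_raises(self):
        config = SynthConfig(n_reports=10, drug_catalog=(("A", 0.0),),
                             ae_catalog=(("X", 0.5, ""),), seed=0)
        with pytest.raises(RuntimeError, match="regeneration"):
            generate_reports(config)


@pytest.fixture(scope="module")
def hand_reports():
    from helpers import make_report
    layout = [
        (5, ["A", "B"], ["X"]),
        (1, ["A", "B"], ["Y"]),
        (4, ["A"], ["X"]),
        (6, ["A"], ["Y"]),
        (2, ["B"], ["X"]),
        (2, ["B"], ["Y"]),
        (2, ["C"], ["X"]),
        (8, ["C"], ["Y"]),
    ]
    out = []
    i = 0
    for count, drugs, aes in layout:
        for _ in range(count):
            out.append(make_report(i, drugs, aes))
            i += 1
    assert len(out) == 30
    return out


class TestHandFixtureEndToEnd:
    """30 hand-written hand_reports; every pipeline number checked against hand
    computation (fractions noted inline)."""

    def test_candidates(self, hand_reports):
        cands = enumerate_candidates(hand_reports, min_n111=3)
        assert [(c.drug1, c.drug2, c.ae, c.n111) for c in cands] == [("A", "B", "X", 5)]

    def test_cells(self, hand_reports):
        t = build_table(hand_reports, TripleCandidate("A", "B", "X"))
        assert t.cells == (5, 1, 4, 6, 2, 2, 2, 8)
        assert (t.n11p, t.n10p, t.n01p, t.n00p) == (6, 10, 4, 10)
        assert (t.npp1, t.nppp) == (13, 30)

    def test_rule_metrics(self, hand_reports):
        m = rule_metrics(build_table(hand_reports, TripleCandidate("A", "B", "X")))
        assert m.support == pytest.approx(5 / 30)
        assert m.confidence == pytest.approx(5 / 6)
        assert m.support_ae == pytest.approx(13 / 30)
        assert m.lift == pytest.approx(25 / 13)
        assert m.conviction == pytest.approx(17 / 5)  # (17/30) / (1/6)

    def test_omega_noren(self, hand_reports):
        # f101=0.4, f011=0.5, f001=0.2 -> 1/(1-g) = 5/3 + 2 - 5/4 = 29/12
        # g = 17/29, e111 = 6*17/29 = 102/29
        ranked = scan_omega(hand_reports, [TripleCandidate("A", "B", "X", 5)], "noren_excess")
        res = ranked[0][1]
        assert res.e111 == pytest.approx(102 / 29, rel=1e-12)
        assert res.omega == pytest.approx(math.log2(5.5 / (102 / 29 + 0.5)), rel=1e-12)
        assert res.omega == pytest.approx(0.453226, abs=1e-6)
        assert res.omega025 == pytest.approx(0.453226 - 1.959964 / (math.log(2) * math.sqrt(5)),
                                             abs=1e-6)
        assert not res.is_signal

    def test_omega_independence(self, hand_reports):
        ranked = scan_omega(hand_reports, [TripleCandidate("A", "B", "X", 5)], "independence")
        res = ranked[0][1]
        assert res.e111 == pytest.approx(2.6)  # 6 * 13/30
        assert res.omega == pytest.approx(math.log2(5.5 / 3.1), rel=1e-12)

    def test_agrees_with_bruteforce_oracle(self, hand_reports):
        cells = brute_cells(hand_reports, "A", "B", "X")
        assert cells == dict(n111=5, n110=1, n101=4, n100=6,
                             n011=2, n010=2, n001=2, n000=8)
        m = brute_metrics(cells)
        assert m["conviction"] == pytest.approx(3.4)
        e = brute_e111(cells, "noren_excess")
        assert e == pytest.approx(102 / 29, rel=1e-9)
        omega, lower = brute_omega(5, e)
        assert omega == pytest.approx(0.453226, abs=1e-6)
        assert lower < 0


class TestRecoveryExperiment:
    @staticmethod
    def small_config(lam, seed=0):
        return SynthConfig(
            n_reports=4_000,
            drug_catalog=(("A", 0.1), ("B", 0.1), ("Base", 0.8)),
            ae_catalog=(("X", 0.005, ""), ("Bg", 0.7, "")),
            injected_effects=(("A", "B", "X", lam),),
            seed=seed,
        )

    def test_replicate_seeds_are_base_plus_offset(self):
        table = recovery_experiment(self.small_config(30.0), n_replicates=3, base_seed=50)
        assert sorted(table["seed"].unique()) == [50, 51, 52]

    def test_reproducible(self):
        a = recovery_experiment(self.small_config(30.0), n_replicates=3, base_seed=9)
        b = recovery_experiment(self.small_config(30.0), n_replicates=3, base_seed=9)
        assert a.equals(b)

    def test_intersection_never_exceeds_single_detectors(self):
        # a filter intersection cannot fire more often than either filter
        table = recovery_experiment(self.small_config(1.0), n_replicates=8, base_seed=0,
                                    track_triples=[("A", "B", "X")])
        assert (table["intersection_detected"] <= table["rule_detected"]).all()
        assert (table["intersection_detected"] <= table["omega_detected"]).all()

    def test_sensitivity_grows_with_n(self):
        import dataclasses
        rates = []
        for n in (1_000, 4_000, 16_000):
            config = dataclasses.replace(self.small_config(30.0), n_reports=n)
            table = recovery_experiment(config, n_replicates=6, base_seed=7)
            rates.append(summarize_recovery(table)["intersection_sensitivity"].iloc[0])
        assert rates[-1] >= rates[0]
        assert rates[-1] == 1.0

    def test_single_drug_effect_mostly_suppressed(self):
        # drug A alone raises X; the pair (A, B) is an artifact and the
        # redundancy filter / excess-risk model suppress it in most replicates
        config = SynthConfig(
            n_reports=8_000,
            drug_catalog=(("A", 0.2), ("B", 0.2), ("Base", 0.8)),
            ae_catalog=(("X", 0.005, ""), ("Bg", 0.7, "")),
            single_drug_effects=(("A", "X", 15.0),),
            seed=0,
        )
        table = recovery_experiment(config, n_replicates=10, base_seed=0,
                                    track_triples=[("A", "B", "X")])
        rate = summarize_recovery(table)["intersection_sensitivity"].iloc[0]
        assert rate <= 0.2

    def test_requires_some_tracked_triple(self):
        import dataclasses
        config = dataclasses.replace(self.small_config(1.0), injected_effects=())
        with pytest.raises(ValueError):
            recovery_experiment(config, n_replicates=1)
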
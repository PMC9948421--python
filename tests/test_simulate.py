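"""Synthetic cohort generator: determinism, invariants, configured
moments, and end-to-end label structure."""
import dataclasses

import numpy as np
import pytest

from tmn.simulate import (
    SimulationConfig,
    _joint_bernoulli_probs,
    draw_survival_covariates,
    patient_covariates,
    simulate_cohort,
    simulate_patients,
    simulate_survival,
    simulate_variants,
)


class TestPatients:
    def test_zero_patients_gives_empty_cohort(self):
        cfg = SimulationConfig(n_patients=0, n_pediatric=0)
        assert simulate_patients(cfg) == []

    def test_same_seed_identical_cohorts(self):
        cfg = SimulationConfig(seed=11)
        a = simulate_patients(cfg)
        b = simulate_patients(cfg)
        assert a == b

    def test_pediatric_count_and_age_ranges(self):
        patients = simulate_patients(SimulationConfig(seed=2))
        pediatric = [p for p in patients if p.pediatric]
        assert len(pediatric) == 7
        assert all(p.age_years < 20 for p in pediatric)
        assert all(20 <= p.age_years <= 85 for p in patients if not p.pediatric)

    def test_prevalence_converges_to_configured_rate(self):
        """Mean del7q prevalence over replicates within 3 SE of 0.434."""
        cfg = SimulationConfig()
        n_rep = 60
        rates = []
        for seed in range(n_rep):
            patients = simulate_patients(SimulationConfig(seed=seed))
            rates.append(np.mean([p.del7q for p in patients]))
        target = cfg.prevalences["del7q"]
        se = np.sqrt(target * (1 - target) / (cfg.n_patients * n_rep))
        assert abs(np.mean(rates) - target) < 3 * se

    def test_del5q_del7q_positive_association(self):
        patients = []
        for seed in range(40):
            patients += simulate_patients(SimulationConfig(seed=seed))
        a = np.array([p.del5q for p in patients])
        b = np.array([p.del7q for p in patients])
        p11 = (a & b).mean()
        assert p11 > a.mean() * b.mean()  # odds ratio > 1 induces coexistence

    def test_joint_probability_solver_matches_odds_ratio(self):
        p11 = _joint_bernoulli_probs(0.283, 0.434, 6.0)
        p10, p01 = 0.283 - p11, 0.434 - p11
        p00 = 1 - p11 - p10 - p01
        assert (p11 * p00) / (p10 * p01) == pytest.approx(6.0)

    def test_nonpositive_odds_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(del5q_del7q_odds_ratio=-1.0)

    def test_joint_probability_respects_frechet_bounds(self):
        for odds in (0.1, 1.0, 6.0, 50.0):
            p11 = _joint_bernoulli_probs(0.283, 0.434, odds)
            assert max(0.0, 0.283 + 0.434 - 1) <= p11 <= min(0.283, 0.434)


class TestVariants:
    def test_carrier_count_matches_configured_rate(self, default_cohort):
        assert len(default_cohort.carriers) == round(0.132 * 53)

    def test_no_artifacts_when_rates_zero(self):
        cfg = SimulationConfig(
            seed=5, strand_bias_rate=0.0, common_polymorphism_rate=0.0,
            pon_artifact_rate=0.0, caller_noise_rate=0.0,
        )
        patients = simulate_patients(cfg)
        cohort = simulate_variants(cfg, patients)
        assert not any(c.truth == "artifact" for c in cohort.calls)

    def test_generated_calls_satisfy_type_invariants(self, default_cohort):
        for c in default_cohort.calls:
            vc = c.to_variant_call()  # VariantCall validates in __post_init__
            assert vc.alt_forward + vc.alt_reverse <= vc.depth
            assert 0 <= vc.vaf <= 1

    def test_carrier_variants_mirrored_into_matched_normals(self, default_cohort):
        cohort = default_cohort
        normals = cohort.normals_by_patient()
        for pid in cohort.carriers & cohort.matched_normal_patients:
            carrier_keys = {
                c.key for c in cohort.calls
                if c.patient_id == pid and c.truth == "germline"
                and c.sample_role == "tmn_initial"
            }
            normal_keys = {nc.key for nc in normals[pid]}
            assert carrier_keys <= normal_keys

    def test_somatic_count_medians_pediatric_below_adult(self):
        counts_ped, counts_adult = [], []
        for seed in range(25):
            cfg = SimulationConfig(seed=seed)
            patients = simulate_patients(cfg, np.random.default_rng(seed))
            cohort = simulate_variants(cfg, patients, np.random.default_rng(seed + 1))
            ped_ids = {p.patient_id for p in patients if p.pediatric}
            per_sample = {}
            for c in cohort.calls:
                if c.truth == "somatic" and c.sample_role == "tmn_initial":
                    per_sample[c.sample_id] = per_sample.get(c.sample_id, 0) + 1
            for p in patients:
                n = per_sample.get(f"{p.patient_id}-A", 0)
                (counts_ped if p.patient_id in ped_ids else counts_adult).append(n)
        assert np.median(counts_ped) <= 2
        assert np.median(counts_adult) == 3
        assert max(counts_adult) <= 7

    def test_tp53_is_most_frequent_somatic_gene(self, default_cohort):
        from collections import Counter

        genes = Counter(
            c.gene for c in default_cohort.calls if c.truth == "somatic"
        )
        assert genes.most_common(1)[0][0] == "TP53"

    def test_every_call_annotated(self, default_cohort):
        for c in default_cohort.calls:
            assert c.key in default_cohort.annotations


class TestSurvivalSimulation:
    def test_null_hazards_give_exchangeable_groups(self):
        cfg = SimulationConfig(
            true_hazard_ratios={"male": 1.0, "radiotherapy": 1.0,
                                "therapy_gt_cut": 1.0, "age_gt_cut": 1.0,
                                "del5q": 1.0},
        )
        from scipy.stats import kstest

        from tmn.survival import logrank_test

        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X = draw_survival_covariates(120, cfg, rng)
            t, d = simulate_survival(cfg, X, rng)
            m = X["male"].to_numpy(dtype=bool)
            _, p = logrank_test(t[m], d[m], t[~m], d[~m])
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_large_sample_hr_recovery_single_covariate(self):
        cfg = SimulationConfig(
            true_hazard_ratios={"male": 4.0, "radiotherapy": 1.0,
                                "therapy_gt_cut": 1.0, "age_gt_cut": 1.0,
                                "del5q": 1.0},
        )
        from tmn.survival import cox_fit

        rng = np.random.default_rng(9)
        X = draw_survival_covariates(2000, cfg, rng)
        t, d = simulate_survival(cfg, X, rng)
        fit = cox_fit(t, d, X[["male"]])
        assert fit.hazard_ratios[0] == pytest.approx(4.0, rel=0.10)

    def test_no_censoring_all_deaths(self):
        cfg = SimulationConfig(censoring_fraction=0.0)
        rng = np.random.default_rng(0)
        X = draw_survival_covariates(200, cfg, rng)
        _, d = simulate_survival(cfg, X, rng)
        assert d.all()

    def test_censoring_fraction_calibrated(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        X = draw_survival_covariates(8000, cfg, rng)
        _, d = simulate_survival(cfg, X, rng)
        assert (1 - d.mean()) == pytest.approx(0.2, abs=0.02)

    def test_times_rounded_to_tenth_of_month(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(2)
        X = draw_survival_covariates(100, cfg, rng)
        t, _ = simulate_survival(cfg, X, rng)
        assert np.allclose(t, np.round(t, 1)) and (t >= 0.1).all()


class TestDeterminism:
    def test_full_cohort_deterministic_under_seed(self):
        a = simulate_cohort(SimulationConfig(seed=3, n_patients=10, n_pediatric=1,
                                             n_matched_normals=3, n_longitudinal=1))
        b = simulate_cohort(SimulationConfig(seed=3, n_patients=10, n_pediatric=1,
                                             n_matched_normals=3, n_longitudinal=1))
        assert [dataclasses.asdict(p) for p in a.patients] == [
            dataclasses.asdict(p) for p in b.patients
        ]
        assert [dataclasses.asdict(c) for c in a.calls] == [
            dataclasses.asdict(c) for c in b.calls
        ]

    def test_different_seed_different_realization(self):
        a = simulate_cohort(SimulationConfig(seed=3, n_patients=10, n_pediatric=1))
        b = simulate_cohort(SimulationConfig(seed=4, n_patients=10, n_pediatric=1))
        assert [c.key for c in a.calls] != [c.key for c in b.calls]

    def test_patient_covariates_match_records(self, default_cohort):
        cfg = default_cohort.config
        X = patient_covariates(default_cohort.patients, cfg)
        p0 = default_cohort.patients[0]
        assert X.loc[p0.patient_id, "male"] == int(p0.sex == "M")
        assert X.loc[p0.patient_id, "age_gt_cut"] == int(p0.age_years > 50)
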
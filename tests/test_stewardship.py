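"""Stewardship evaluation: filters, classifiers, sampling, statistics."""

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from empirx.advisor import AdviceOutcome, AdvisedDrug, DoseDecision
from empirx.patient_data import Prescription
from empirx.stewardship import (
    PROPHYLAXIS_RULES,
    adherence_rate_pct,
    classify_adherence,
    classify_prophylaxis,
    evaluate,
    extrapolate_eligible,
    filter_cohort,
    proportion_ci,
    proportional_stratified_sample,
    trunc1,
    usage_rate_pct,
)
from empirx.synthetic import CohortConfig, generate_cohort

from conftest import NOW, make_patient

T = datetime(2017, 3, 1, 10, 0)


def rx(drug="amoxicillin", atc="J01CA04", amount=500.0, unit="mg", route="oral",
       start=T, hours=None, days=5, interval=8, **kw):
    stop = start + (timedelta(hours=hours) if hours else timedelta(days=days))
    return Prescription(atc=atc, drug=drug, dose_amount=amount, dose_unit=unit,
                        route=route, start=start, stop=stop,
                        interval_hours=interval, **kw)


class TestProphylaxis:
    def test_short_course_is_prophylaxis(self, patient):
        call = classify_prophylaxis(rx(hours=36), patient)
        assert call.is_prophylaxis and call.rule == "duration_lt_48h"

    def test_exactly_48h_is_not_short_course(self, patient):
        assert not classify_prophylaxis(rx(hours=48), patient).is_prophylaxis

    def test_cotrimoxazole_480_regardless_of_duration(self, patient):
        call = classify_prophylaxis(
            rx(drug="cotrimoxazole", atc="J01EE01", amount=480, days=10), patient)
        assert call.rule == "cotrimoxazole_480"

    def test_cotrimoxazole_960_is_not_the_480_rule(self, patient):
        call = classify_prophylaxis(
            rx(drug="cotrimoxazole", atc="J01EE01", amount=960, days=10), patient)
        assert not call.is_prophylaxis

    def test_perioperative_cefazolin_without_indication(self, patient):
        call = classify_prophylaxis(
            rx(drug="cefazolin", atc="J01DB04", amount=1000, route="iv", days=3,
               perioperative_context="intra", clear_indication=False), patient)
        assert call.rule == "perioperative_cefazolin"

    def test_perioperative_cefazolin_with_clear_indication_is_therapy(self, patient):
        call = classify_prophylaxis(
            rx(drug="cefazolin", atc="J01DB04", amount=1000, route="iv", days=3,
               perioperative_context="intra", clear_indication=True), patient)
        assert not call.is_prophylaxis

    @pytest.mark.parametrize("tag", ["sdd", "neutropenia", "copd"])
    def test_protocol_tags(self, tag, patient):
        call = classify_prophylaxis(rx(days=14, protocol_tag=tag), patient)
        assert call.rule == tag

    def test_pheneticillin_within_two_years_of_splenectomy(self, patient):
        call = classify_prophylaxis(
            rx(drug="pheneticillin", atc="J01CE05", amount=250, days=30,
               splenectomy_date=T.date() - timedelta(days=400)), patient)
        assert call.rule == "pheneticillin_post_splenectomy"

    def test_pheneticillin_three_years_after_splenectomy_is_therapy(self, patient):
        call = classify_prophylaxis(
            rx(drug="pheneticillin", atc="J01CE05", amount=250, days=7,
               splenectomy_date=T.date() - timedelta(days=3 * 365)), patient)
        assert not call.is_prophylaxis

    def test_agrees_with_all_rules_oracle_on_random_prescriptions(self, patient):
        """First-match classification vs an oracle evaluating every rule
        independently, over 10,000 random prescriptions."""
        rng = np.random.default_rng(42)
        drugs = [("amoxicillin", "J01CA04"), ("cotrimoxazole", "J01EE01"),
                 ("cefazolin", "J01DB04"), ("pheneticillin", "J01CE05"),
                 ("ceftriaxone", "J01DD04")]
        contexts = [None, "pre", "intra", "post"]
        tags = [None, "sdd", "neutropenia", "copd"]
        for _ in range(10_000):
            drug, atc = drugs[rng.integers(len(drugs))]
            p = rx(
                drug=drug, atc=atc,
                amount=float(rng.choice([250, 480, 960, 1000])),
                hours=int(rng.integers(6, 300)),
                perioperative_context=contexts[rng.integers(4)],
                clear_indication=bool(rng.integers(2)),
                protocol_tag=tags[rng.integers(4)],
                splenectomy_date=(
                    T.date() - timedelta(days=int(rng.integers(0, 1500)))
                    if rng.random() < 0.5 else None
                ),
            )
            call = classify_prophylaxis(p, patient)

            # independent oracle: evaluate all definitions, first match wins
            matching = []
            if p.stop - p.start < timedelta(hours=48):
                matching.append("duration_lt_48h")
            if p.drug == "cotrimoxazole" and p.dose_amount == 480 and p.dose_unit == "mg":
                matching.append("cotrimoxazole_480")
            if p.drug == "cefazolin" and p.perioperative_context and not p.clear_indication:
                matching.append("perioperative_cefazolin")
            if p.protocol_tag in ("sdd", "neutropenia", "copd"):
                matching.append(p.protocol_tag)
            if (p.drug == "pheneticillin" and p.splenectomy_date
                    and (p.start.date() - p.splenectomy_date).days <= 730):
                matching.append("pheneticillin_post_splenectomy")
            matching.sort(key=PROPHYLAXIS_RULES.index)

            assert call.is_prophylaxis == bool(matching)
            assert call.rule == (matching[0] if matching else "none")


class TestFilterCohort:
    def test_prophylaxis_only_patient_excluded(self):
        p = make_patient(prescriptions=[rx(drug="cefazolin", atc="J01DB04",
                                           route="iv", hours=36,
                                           perioperative_context="pre",
                                           clear_indication=False)])
        assert filter_cohort([p]) == []

    def test_one_day_admission_excluded(self):
        p = make_patient(admission_start=datetime(2017, 3, 1, 8),
                         admission_end=datetime(2017, 3, 2, 8),
                         prescriptions=[rx()])
        assert filter_cohort([p]) == []

    def test_minor_excluded(self):
        p = make_patient(birth_date=date(2002, 1, 1), prescriptions=[rx()])
        assert filter_cohort([p]) == []

    def test_no_j01_excluded(self):
        p = make_patient(prescriptions=[rx(drug="fluconazole", atc="J02AC01")])
        assert filter_cohort([p]) == []

    def test_adult_with_therapeutic_course_included(self):
        p = make_patient(prescriptions=[rx(drug="ciprofloxacin", atc="J01MA02",
                                           days=7)])
        assert filter_cohort([p]) == [p]


def advice(*drugs):
    return AdviceOutcome(
        kind="regimen",
        drugs=[
            AdvisedDrug(drug=d, route=route,
                        dose=DoseDecision(drug=d, dose_amount=amount,
                                          dose_unit=unit, interval_hours=interval))
            for d, route, amount, unit, interval in drugs
        ],
        duration_days=7,
    )


PIPTAZO = ("piperacillin-tazobactam", "iv", 4.5, "g", 8)
GENTA = ("gentamicin", "iv", 320.0, "mg", 24)


class TestAdherence:
    def test_identical_prescription_is_complete(self):
        out = classify_adherence(
            advice(PIPTAZO),
            [rx(drug="piperacillin-tazobactam", atc="J01CR05", amount=4.5,
                unit="g", route="iv", interval=8, start=T + timedelta(hours=2))],
            T,
        )
        assert out.category == "complete"
        assert out.matched == ["piperacillin-tazobactam"]

    def test_unit_normalization_g_vs_mg(self):
        out = classify_adherence(
            advice(PIPTAZO),
            [rx(drug="piperacillin-tazobactam", atc="J01CR05", amount=4500,
                unit="mg", route="iv", interval=8, start=T + timedelta(hours=1))],
            T,
        )
        assert out.category == "complete"

    def test_one_of_two_drugs_is_partial(self):
        out = classify_adherence(
            advice(PIPTAZO, GENTA),
            [rx(drug="piperacillin-tazobactam", atc="J01CR05", amount=4.5,
                unit="g", route="iv", interval=8, start=T + timedelta(hours=2))],
            T,
        )
        assert out.category == "partial"
        assert out.missing == ["gentamicin"]

    def test_different_route_is_partial(self):
        out = classify_adherence(
            advice(("ciprofloxacin", "iv", 400.0, "mg", 12)),
            [rx(drug="ciprofloxacin", atc="J01MA02", amount=400, unit="mg",
                route="oral", interval=12, start=T + timedelta(hours=2))],
            T,
        )
        assert out.category == "partial"
        assert out.mismatched == {"ciprofloxacin": ["route"]}

    def test_different_interval_is_partial(self):
        out = classify_adherence(
            advice(PIPTAZO),
            [rx(drug="piperacillin-tazobactam", atc="J01CR05", amount=4.5,
                unit="g", route="iv", interval=12, start=T + timedelta(hours=2))],
            T,
        )
        assert out.category == "partial"
        assert "interval" in out.mismatched["piperacillin-tazobactam"]

    def test_disjoint_drug_is_none(self):
        out = classify_adherence(
            advice(("nitrofurantoin", "oral", 100.0, "mg", 12)),
            [rx(drug="ciprofloxacin", atc="J01MA02", amount=500, unit="mg",
                route="oral", interval=12, start=T + timedelta(hours=2))],
            T,
        )
        assert out.category == "none"

    def test_prescription_outside_window_ignored(self):
        out = classify_adherence(
            advice(PIPTAZO),
            [rx(drug="piperacillin-tazobactam", atc="J01CR05", amount=4.5,
                unit="g", route="iv", interval=8, start=T + timedelta(hours=30))],
            T,
        )
        assert out.category == "none"

    def test_consult_advice_not_classifiable(self):
        with pytest.raises(ValueError):
            classify_adherence(AdviceOutcome(kind="consult_id"), [], T)

    def test_exactly_one_category_over_random_pairs(self):
        """Partition property: randomized advice/prescription pairs always get
        exactly one category, consistent with the match details."""
        rng = np.random.default_rng(7)
        pool = [PIPTAZO, GENTA, ("ciprofloxacin", "iv", 400.0, "mg", 12),
                ("nitrofurantoin", "oral", 100.0, "mg", 12)]
        for _ in range(500):
            k = int(rng.integers(1, 3))
            idx = rng.choice(len(pool), size=k, replace=False)
            adv = advice(*[pool[i] for i in idx])
            rxs = []
            for _ in range(int(rng.integers(0, 4))):
                d, route, amount, unit, interval = pool[int(rng.integers(len(pool)))]
                rxs.append(rx(
                    drug=d, atc="J01XX00", amount=amount * float(rng.choice([1, 2])),
                    unit=unit, route=route if rng.random() < 0.7 else
                    ("oral" if route == "iv" else "iv"),
                    interval=interval, start=T + timedelta(hours=int(rng.integers(0, 30))),
                ))
            out = classify_adherence(adv, rxs, T)
            assert out.category in ("complete", "partial", "none")
            n_advised = len(adv.drugs)
            assert len(out.matched) + len(out.mismatched) + len(out.missing) == n_advised
            if out.category == "complete":
                assert len(out.matched) == n_advised
            if out.category == "none":
                assert len(out.missing) == n_advised


class TestStratifiedSample:
    def _cohort(self, sizes: dict):
        cohort = []
        for ward, size in sizes.items():
            cohort += [make_patient(patient_id=f"{ward}-{i}", ward=ward)
                       for i in range(size)]
        return cohort

    def test_exact_proportionality(self):
        sample = proportional_stratified_sample(self._cohort({"a": 90, "b": 10}),
                                                n=10, seed=0)
        wards = [p.ward for p in sample]
        assert wards.count("a") == 9 and wards.count("b") == 1

    def test_same_seed_identical_sample(self):
        cohort = self._cohort({"a": 50, "b": 30, "c": 20})
        s1 = proportional_stratified_sample(cohort, n=25, seed=13)
        s2 = proportional_stratified_sample(cohort, n=25, seed=13)
        assert [p.patient_id for p in s1] == [p.patient_id for p in s2]

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            proportional_stratified_sample(self._cohort({"a": 5}), n=6, seed=0)

    def test_largest_remainder_over_many_strata(self):
        """50 strata, n = 248: counts sum exactly and deviate < 1 from quota."""
        rng = np.random.default_rng(3)
        sizes = {f"w{i:02d}": int(rng.integers(10, 120)) for i in range(50)}
        cohort = self._cohort(sizes)
        sample = proportional_stratified_sample(cohort, n=248, seed=8)
        assert len(sample) == 248
        total = len(cohort)
        counts: dict[str, int] = {}
        for p in sample:
            counts[p.ward] = counts.get(p.ward, 0) + 1
        for ward, size in sizes.items():
            quota = 248 * size / total
            assert abs(counts.get(ward, 0) - quota) < 1


class TestProportionStatistics:
    def test_point_estimate_prints_40_3(self):
        point, lo, hi = proportion_ci(100, 248)
        assert round(point, 1) == 40.3

    def test_degenerate_zero_clips(self):
        assert proportion_ci(0, 50) == (0.0, 0.0, 0.0)

    def test_bounds_match_closed_form_wald(self):
        point, lo, hi = proportion_ci(100, 248)
        p = 100 / 248
        half = 1.959963984540054 * math.sqrt(p * (1 - p) / 248)
        assert lo == pytest.approx(100 * (p - half), abs=0.05)
        assert hi == pytest.approx(100 * (p + half), abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)

    def test_extrapolation_arithmetic(self):
        assert extrapolate_eligible(3349, 100, 248) == 1349

    def test_usage_rate_formula(self):
        assert round(usage_rate_pct(184, 15, 1349), 1) == 12.5

    def test_adherence_rate_truncates(self):
        assert adherence_rate_pct(91, 23, 169) == 67.4
        assert trunc1(67.499) == 67.4


class TestEvaluate:
    def test_report_on_synthetic_pipeline(self):
        cfg = CohortConfig(n_patients=800, seed=21)
        cohort, sessions, truth = generate_cohort(cfg)
        filtered = filter_cohort(cohort)
        report = evaluate(filtered, sessions, sample_n=200, seed=5)
        assert report.n_sample == 200
        assert report.n_sessions_total == len(sessions)
        assert report.n_advice == report.n_regimen_advice + report.n_consult_advice
        assert (report.n_complete + report.n_partial + report.n_none
                == report.n_regimen_advice)
        # invariant: usage = 100 * (total - test) / extrapolated
        expected = 100 * (report.n_sessions_total - report.n_sessions_test) \
            / report.n_eligible_extrapolated
        assert report.usage_pct == pytest.approx(expected, abs=0.05)
        assert "CDSS uses" in report.to_text()

    def test_zero_sessions(self):
        cohort, _, _ = generate_cohort(CohortConfig(n_patients=60, seed=2,
                                                    session_rate=0.0))
        filtered = filter_cohort(cohort)
        report = evaluate(filtered, [], sample_n=20, seed=1)
        assert report.usage_pct == 0.0
        assert report.n_complete == report.n_partial == report.n_none == 0
        assert report.adherence_followed_pct == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [], sample_n=0, seed=0)

    def test_wald_coverage_of_configured_prevalence(self):
        """500 seeded stratified samples of n=248 from a cohort generated at
        40% eligible prevalence: the 95% Wald interval covers 40% in >= 93%
        of replicates (slight undercoverage tolerated)."""
        cfg = CohortConfig(n_patients=3349, seed=99, eligible_prevalence=0.40,
                           prophylaxis_only_rate=0.0, session_rate=0.0,
                           test_session_rate=0.0)
        cohort, _, truth = generate_cohort(cfg)
        eligible_ids = {pid for pid, t in truth.patients.items() if t.eligible}
        covered = 0
        for rep in range(500):
            sample = proportional_stratified_sample(cohort, n=248, seed=10_000 + rep)
            k = sum(p.patient_id in eligible_ids for p in sample)
            _, lo, hi = proportion_ci(k, 248)
            covered += lo <= 40.0 <= hi
        assert covered / 500 >= 0.93
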
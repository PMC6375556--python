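"""Trial endpoints, exact binomial design, Kaplan-Meier and exposure."""

import numpy as np
import pytest

from neoexome.clinical import (
    DesignSpec,
    ae_table,
    design_operating_characteristics,
    dose_intensity,
    km_dfs,
    read_outcomes,
    response_rates,
    write_outcomes,
)
from neoexome.records import PatientOutcome
from neoexome.synthetic import CohortSpec, generate_cohort


def _patient(pid="P1", **overrides):
    base = dict(
        patient_id=pid,
        subtype="TNBC",
        breast_pcr=False,
        breast_ln_pcr=False,
        ypt0_ypn0=False,
        ncr=False,
        surgery="mastectomy",
        dfs_months=20.0,
        dfs_event=False,
        planned_dose=125.0,
        delivered_dose=125.0,
    )
    base.update(overrides)
    return PatientOutcome(**base)


class TestResponseRates:
    def test_default_cohort_reproduces_reported_rates(self):
        rates = response_rates(generate_cohort())
        assert rates["breast_pcr"]["percent"] == pytest.approx(55.0)
        assert rates["breast_ln_pcr"]["percent"] == pytest.approx(45.0)
        assert rates["pcr_or_ncr"]["percent"] == pytest.approx(65.0)
        assert rates["ncr"]["percent"] == pytest.approx(10.0)
        assert rates["ypt0_ypn0"]["percent"] == pytest.approx(32.5)
        assert rates["breast_conserving"]["percent"] == pytest.approx(47.5)
        by = rates["by_subtype"]
        assert by["HER2_amplified"]["breast_pcr"]["n"] == 12
        assert by["TNBC"]["breast_pcr"]["n"] == 7
        assert by["HR_pos_HER2_neg_RS_ge_25"]["breast_pcr"]["percent"] == pytest.approx(30.0)

    def test_subtype_numerators_sum_to_overall(self):
        rates = response_rates(generate_cohort())
        total = sum(v["breast_pcr"]["n"] for v in rates["by_subtype"].values())
        assert total == rates["breast_pcr"]["n"]

    def test_all_negative_cohort(self):
        spec = CohortSpec(
            breast_pcr={k: 0 for k in CohortSpec().breast_pcr},
            breast_ln_pcr={k: 0 for k in CohortSpec().breast_ln_pcr},
            n_ypt0_ypn0=0, n_ncr=0,
        )
        rates = response_rates(generate_cohort(spec))
        assert rates["breast_pcr"]["percent"] == 0.0 and rates["ncr"]["n"] == 0

    def test_unknown_subtype_rejected(self):
        bad = _patient(subtype="TNBC")
        bad.subtype = "luminal"
        with pytest.raises(ValueError, match="unknown subtype"):
            response_rates([bad])


class TestDesign:
    def test_exact_tails_round_to_stated_operating_characteristics(self):
        alpha, power = design_operating_characteristics(DesignSpec())
        assert round(100 * alpha) == 6
        assert round(100 * power) == 87

    def test_zero_threshold_gives_certainty(self):
        alpha, power = design_operating_characteristics(DesignSpec(r=0))
        assert alpha == 1.0 and power == 1.0

    def test_monte_carlo_agreement(self):
        """Exact tails within 0.3 percentage points of a large simulation."""
        spec = DesignSpec()
        alpha, power = design_operating_characteristics(spec)
        rng = np.random.default_rng(123)
        draws0 = rng.binomial(spec.n, spec.p0, size=1_000_000)
        draws1 = rng.binomial(spec.n, spec.p1, size=1_000_000)
        assert abs((draws0 >= spec.r).mean() - alpha) < 0.003
        assert abs((draws1 >= spec.r).mean() - power) < 0.003

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(p0=0.5, p1=0.3)


def product_limit(times, events):
    """Hand-computed Kaplan-Meier oracle: (event time, S(t)) pairs."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, out = 1.0, []
    for t in sorted(set(times[events.astype(bool)])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events.astype(bool)).sum())
        s *= 1 - d / at_risk
        out.append((t, s))
    return out


class TestKaplanMeier:
    def test_no_events_median_not_reached(self):
        cohort = [_patient(pid=f"P{i}", dfs_months=12 + i) for i in range(5)]
        curve, median = km_dfs(cohort)
        assert median is None
        assert (curve["survival"] == 1.0).all()

    def test_single_event_among_five(self):
        cohort = [_patient(pid="P0", dfs_months=5.0, dfs_event=True)]
        cohort += [_patient(pid=f"P{i}", dfs_months=5.0) for i in range(1, 5)]
        curve, _ = km_dfs(cohort)
        s5 = curve.loc[curve["time"] == 5.0, "survival"].iloc[0]
        assert s5 == pytest.approx(0.8)

    def test_six_row_worked_example_matches_hand_oracle(self):
        times = [5.0, 8.0, 12.0, 16.0, 20.0, 24.0]
        events = [1, 0, 1, 0, 1, 0]
        cohort = [_patient(pid=f"P{i}", dfs_months=t, dfs_event=bool(e))
                  for i, (t, e) in enumerate(zip(times, events))]
        curve, median = km_dfs(cohort)
        expected = product_limit(times, events)
        assert expected == [(5.0, pytest.approx(5 / 6)),
                            (12.0, pytest.approx(5 / 6 * 3 / 4)),
                            (20.0, pytest.approx(5 / 6 * 3 / 4 * 1 / 2))]
        lookup = dict(zip(curve["time"], curve["survival"]))
        for t, s in expected:
            assert lookup[t] == pytest.approx(s)
        assert median == 20.0  # first time S(t) <= 0.5

    def test_progression_on_treatment_not_an_event(self):
        cohort = [_patient(pid="P0", dfs_months=3.0, dfs_event=True, progressed_on_treatment=True)]
        cohort += [_patient(pid=f"P{i}", dfs_months=10.0) for i in range(1, 4)]
        curve, _ = km_dfs(cohort)
        assert (curve["survival"] == 1.0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_dfs([_patient(dfs_months=-1.0)])

    def test_curve_is_nonincreasing_from_one(self):
        cohort = generate_cohort()
        curve, _ = km_dfs(cohort)
        surv = curve["survival"].to_numpy()
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 1e-12).all()


class TestExposure:
    def test_rdi_identities(self):
        full = _patient(pid="A")
        none = _patient(pid="B", delivered_dose=0.0)
        result = dose_intensity([full, none])
        per = result["per_patient"].set_index("patient_id")["rdi"]
        assert per["A"] == 1.0 and per["B"] == 0.0

    def test_default_cohort_rdi_fraction(self):
        result = dose_intensity(generate_cohort())
        assert result["at_or_above_threshold"]["n"] == 35
        assert result["at_or_above_threshold"]["percent"] == pytest.approx(87.5)

    def test_zero_planned_dose_rejected(self):
        with pytest.raises(ValueError, match="planned"):
            dose_intensity([_patient(planned_dose=0.0)])


class TestAdverseEvents:
    def test_patient_counted_once_per_term_at_worst_grade(self):
        p = _patient(adverse_events=[("Nausea", 1), ("Nausea", 3)])
        others = [_patient(pid=f"P{i}") for i in range(2, 5)]
        table = ae_table([p, *others])
        row = table.set_index("term").loc["Nausea"]
        assert row["any_grade_n"] == 1 and row["grade_ge3_n"] == 1

    def test_rare_low_grade_terms_filtered(self):
        p = _patient(adverse_events=[("Rash", 1)])
        others = [_patient(pid=f"P{i}") for i in range(2, 20)]
        assert ae_table([p, *others]).empty  # 1/19 < 10%, no grade >= 3

    def test_empty_cohort_events(self):
        assert ae_table([_patient()]).empty

    def test_default_cohort_matches_marginals(self):
        from neoexome.refdata import AE_MARGINALS

        table = ae_table(generate_cohort()).set_index("term")
        for term, (any_n, ge3_n) in AE_MARGINALS.items():
            assert table.loc[term, "any_grade_n"] == any_n
            assert table.loc[term, "grade_ge3_n"] == ge3_n

    def test_bad_grade_rejected(self):
        with pytest.raises(ValueError, match="grade"):
            ae_table([_patient(adverse_events=[("Nausea", 6)])])


def test_outcomes_csv_round_trip(tmp_path):
    cohort = generate_cohort()
    path = tmp_path / "outcomes.csv"
    write_outcomes(cohort, path)
    back = read_outcomes(path)
    assert len(back) == 40
    assert [p.patient_id for p in back] == [p.patient_id for p in cohort]
    assert back[0].adverse_events == cohort[0].adverse_events
    assert back[0].dfs_months == cohort[0].dfs_months
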
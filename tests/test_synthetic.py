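"""Synthetic study generator: determinism, noise calibration, censoring and
round-trip consistency with the preprocessing path."""

import dataclasses

import numpy as np
import pytest

from pdepkpd import published as pub
from pdepkpd import simulate_tnf
from pdepkpd.synthetic import (
    Arm,
    StudyDesign,
    default_design,
    endotoxemia_conc_fns,
    generate_cia,
    generate_endotoxemia,
    generate_pk,
    generate_plate,
    relative_paw_table,
    to_series,
    PAW_SCHEMA,
    PK_SCHEMA,
    PLATE_SCHEMA,
)


class TestDesigns:
    def test_default_schedules_match_study(self):
        pk_lewis = default_design("pk_lewis")
        assert pk_lewis.schedule["GRMS-55"] == (5, 15, 30, 60, 90, 120)
        assert pk_lewis.schedule["rolipram"] == (10, 20, 40, 80, 120, 160, 220)
        endo = default_design("endotoxemia")
        assert endo.schedule["LSF_PTX"] == (0, 15, 30, 60, 90, 120, 180)
        assert endo.schedule["GRMS-55"] == (30, 60, 90, 120, 180)
        cia = default_design("cia")
        assert cia.schedule == (0, 5, 7, 11, 15, 18, 20, 22, 26, 30, 33, 36)
        assert all(arm.n == 6 for arm in cia.arms)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            default_design("histology")
        with pytest.raises(ValueError):
            StudyDesign("histology", (), (), cv=0.1)


class TestGeneratePk:
    def test_deterministic_under_seed(self):
        a = generate_pk(seed=11)
        b = generate_pk(seed=11)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = generate_pk(seed=12)
        assert a.to_csv(index=False) != c.to_csv(index=False)

    def test_zero_cv_reproduces_model(self):
        design = dataclasses.replace(default_design("pk_wistar"), cv=0.0)
        frame = generate_pk(design, seed=0)
        series = to_series(frame, "GRMS-55_IV20_1", "GRMS-55")
        t, c = series.quantified()
        expected = 20.0 / 1.59 * np.exp(-(0.051 / 1.59) * t)
        np.testing.assert_allclose(c, expected, rtol=1e-6)

    def test_schema_and_censoring(self):
        frame = generate_pk(seed=5)
        assert list(frame.columns) == PK_SCHEMA
        flagged = frame[frame["censored"] == 1]
        assert flagged["conc"].isna().all()
        clean = frame[(frame["censored"] == 0) & frame["loq"].notna()]
        assert (clean["conc"] >= clean["loq"]).all()

    def test_empirical_cv_matches_request(self):
        """Law of large numbers: with CV=0.10 and 1000 subjects the observed
        between-subject CV at a fixed time point is close to 0.10."""
        design = StudyDesign(
            "pk_wistar", (Arm("GRMS-55", dose=20.0, route="IV", n=1000),),
            {"GRMS-55": (5, 60)}, cv=0.10, loq=None,
        )
        frame = generate_pk(design, seed=21)
        at5 = frame[frame["time_min"] == 5]["conc"]
        cv = at5.std() / at5.mean()
        assert 0.08 < cv < 0.12


class TestGenerateEndotoxemia:
    def test_control_zero_noise_equals_model(self):
        design = StudyDesign(
            "endotoxemia", (Arm("vehicle", n=1),),
            pub.ENDOTOXEMIA_SCHEDULE, cv=0.0, loq=pub.LOQ_TNF_NG_L,
        )
        frame = generate_endotoxemia(design, seed=0)
        series = to_series(frame, "vehicle_1", "TNFa")
        truth = simulate_tnf({}, pub.ENDOTOXEMIA["LSF_PTX"], series.times)
        t, c = series.quantified()
        keep = ~series.censored
        np.testing.assert_allclose(c, truth.conc[keep], rtol=1e-6)

    def test_strong_drug_suppresses_below_control(self):
        sched = {"LSF_PTX": pub.ENDOTOXEMIA_SCHEDULE["LSF_PTX"]}
        design = StudyDesign(
            "endotoxemia", (Arm("vehicle", n=1), Arm("LSF", dose=80.0, route="IV", n=1)),
            sched, cv=0.0, loq=None,
        )
        strong = {
            "LSF_PTX": dataclasses.replace(
                pub.ENDOTOXEMIA["LSF_PTX"],
                inhibition={
                    "LSF": dataclasses.replace(
                        pub.ENDOTOXEMIA["LSF_PTX"].inhibition["LSF"], ic50=1e-9
                    ),
                    "PTX": pub.ENDOTOXEMIA["LSF_PTX"].inhibition["PTX"],
                },
            )
        }
        frame = generate_endotoxemia(design, pd_params=strong, seed=0)
        ctrl = frame[frame["subject_id"] == "vehicle_1"].set_index("time_min")["conc"]
        trt = frame[frame["subject_id"] == "LSF_1"].set_index("time_min")["conc"]
        post = ctrl.index > 0
        assert np.all(trt[post] < ctrl[post])

    def test_mean_trajectory_covers_truth(self):
        """n=4 at 15% CV: the group mean stays within 2 SEM of the true
        curve at most time points."""
        design = StudyDesign(
            "endotoxemia", (Arm("vehicle", n=4),),
            pub.ENDOTOXEMIA_SCHEDULE, cv=0.15, loq=None,
        )
        frame = generate_endotoxemia(design, seed=2)
        truth = simulate_tnf(
            {}, pub.ENDOTOXEMIA["LSF_PTX"],
            np.asarray(pub.ENDOTOXEMIA_SCHEDULE["LSF_PTX"], dtype=float),
        )
        grouped = frame.groupby("time_min")["conc"]
        mean, sem = grouped.mean(), grouped.std() / np.sqrt(4)
        covered = np.abs(mean.to_numpy() - truth.conc) <= 2 * sem.to_numpy()
        assert covered.mean() >= 0.8


class TestGenerateCia:
    def test_requires_control_arm(self):
        design = StudyDesign(
            "cia", (Arm("GRMS-55", dose=50.0, route="IP", n=2),),
            pub.CIA_MEASUREMENT_DAYS, cv=0.1,
        )
        with pytest.raises(ValueError, match="vehicle"):
            generate_cia(design)

    def test_zero_noise_round_trip(self):
        """Raw diameters invert exactly back to the simulated relative
        swelling through the preprocessing path."""
        from pdepkpd.synthetic import cia_conc_fn
        from pdepkpd import simulate_cia

        design = StudyDesign(
            "cia", (Arm("vehicle", n=1), Arm("GRMS-55", dose=50.0, route="IP", n=1)),
            pub.CIA_MEASUREMENT_DAYS, cv=0.0,
        )
        frame = generate_cia(design, seed=3)
        rel = relative_paw_table(frame)
        days = np.asarray(pub.CIA_MEASUREMENT_DAYS, dtype=float)
        ctrl_truth = simulate_cia(
            dataclasses.replace(pub.CIA["GRMS-55"], ic50=None), days
        )
        got = rel[rel["animal_id"] == "vehicle_1"].sort_values("day")["rel_paw"]
        np.testing.assert_allclose(got.to_numpy(), ctrl_truth, atol=1e-8)
        trt_truth = simulate_cia(
            pub.CIA["GRMS-55"], days, conc_fn=cia_conc_fn("GRMS-55"),
            dose_days=tuple(range(20, 40)),
        )
        got_t = rel[rel["animal_id"] == "GRMS-55_1"].sort_values("day")["rel_paw"]
        np.testing.assert_allclose(got_t.to_numpy(), trt_truth, atol=1e-7)

    def test_day_zero_relative_is_one(self):
        frame = generate_cia(seed=9)
        rel = relative_paw_table(frame)
        day0 = rel[rel["day"] == 0]
        np.testing.assert_allclose(day0["rel_paw"], 1.0, atol=1e-12)

    def test_schema_and_determinism(self):
        a = generate_cia(seed=4)
        assert list(a.columns) == PAW_SCHEMA + ["arm"]
        b = generate_cia(seed=4)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_near_universal_onset_by_treatment_start(self):
        """Nearly all control animals show frank swelling by the day
        treatment started.  The observed study criterion was >150% of day 0
        at day 20; the progression curve implied by the published parameters
        tops out near 151%, reaching ~147% at day 20, so the generator is
        checked against a 140% threshold that the model does guarantee."""
        design = StudyDesign(
            "cia", (Arm("vehicle", n=10), Arm("GRMS-55", dose=50.0, route="IP", n=1)),
            pub.CIA_MEASUREMENT_DAYS, cv=0.02,
        )
        frame = generate_cia(design, seed=6, animal_cv=0.05)
        rel = relative_paw_table(frame)
        by20 = rel[(rel["day"] <= 20) & rel["animal_id"].str.startswith("vehicle")]
        onset = by20.groupby("animal_id")["rel_paw"].max() > 1.4
        assert onset.mean() >= 0.9


class TestGeneratePlate:
    def test_zero_noise_identities(self):
        design = dataclasses.replace(default_design("plate_assay"), cv=0.0)
        truth = pub.PDE_HILL["GRMS-55"]["PDE7A"]
        frame = generate_plate(design, hill=truth, seed=0)
        assert list(frame.columns) == PLATE_SCHEMA
        controls = frame[frame["is_control"] == 1]["reading"]
        np.testing.assert_allclose(controls, 100.0)
        at_ic50 = frame[np.isclose(frame["conc_uM"], truth.IC50)]
        if len(at_ic50):
            np.testing.assert_allclose(at_ic50["reading"], 100 - truth.Imax / 2)
        # readings at the highest concentration approach E0 - Imax
        top = frame[frame["conc_uM"] == frame["conc_uM"].max()]["reading"]
        assert np.all(top < 100 - truth.Imax / 2)

    def test_quadruplicate_wells(self):
        frame = generate_plate(seed=1)
        counts = frame[frame["is_control"] == 0].groupby("conc_uM").size()
        assert (counts == 4).all()


def test_ptx_dosing_yields_metabolite_only_exposure():
    fns = endotoxemia_conc_fns("PTX", 40.0)
    assert fns["LSF"](30.0) == pytest.approx(0.0, abs=1e-12)
    assert fns["PTX"](30.0) > 1.0
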
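"""Synthetic cohort generator: determinism, closed loops, parameter recovery."""

import warnings

import numpy as np
import pytest

from gxtrans import metabolic as mb
from gxtrans import simulate as sim
from gxtrans import stats as gs
from gxtrans import translation as tr
from gxtrans.errors import SupramaximalWarning


def quiet_mets(w):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mb.workload_mets(w)


class TestCohort:
    def test_seeded_determinism(self):
        a = sim.make_cohort(20, seed=1)
        b = sim.make_cohort(20, seed=1)
        assert a == b
        c = sim.make_cohort(20, seed=2)
        assert a != c

    def test_point_ranges_collapse_to_exact_parameters(self):
        (m,) = sim.make_cohort(1, seed=0, hr_rest=62.0, hr_max=185.0, max_mets=12.0)
        assert (m.hr_rest, m.hr_max, m.max_mets) == (62.0, 185.0, 12.0)

    def test_uniform_sampling_mean(self):
        cohort = sim.make_cohort(1000, seed=3, hr_max=(180.0, 194.0))
        mean = np.mean([m.hr_max for m in cohort])
        assert mean == pytest.approx(187.0, abs=0.5)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            sim.make_cohort(5, seed=0, hr_max=(194.0, 180.0))
        with pytest.raises(ValueError):
            sim.make_cohort(0, seed=0)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            sim.PhysiologyModel(hr_rest=80, hr_max=70, max_mets=12)
        with pytest.raises(ValueError):
            sim.PhysiologyModel(hr_rest=60, hr_max=180, max_mets=12, true_kappa=1.5)


class TestResponseCurve:
    def test_anchors(self):
        c = sim.ResponseCurve(60.0, 180.0, 13.0)
        assert c.hr_of_mets(1.0) == 60.0
        assert c.hr_of_mets(13.0) == 180.0
        assert c.rpe_of_hrr(0.0) == 6.0
        assert c.rpe_of_hrr(1.0) == 20.0

    def test_inverse(self):
        c = sim.ResponseCurve(60.0, 180.0, 13.0)
        for m in (1.0, 4.2, 9.9, 13.0):
            assert c.mets_of_hr(c.hr_of_mets(m)) == pytest.approx(m, abs=1e-12)


class TestSimulateGxt:
    def test_noise_free_maximal_endpoint(self):
        # capacity exactly equal to a stage demand: test ends there at hr_max
        cap = mb.workload_mets(mb.Workload(80.4, 0.10))
        model = sim.PhysiologyModel(
            hr_rest=70, hr_max=160, max_mets=cap,
            hr_noise_sd=0.0, rpe_noise_sd=0.0, seed=0,
        )
        rec = sim.simulate_gxt(model)
        assert not rec.submaximal
        assert rec.hr_series[-1][1] == 160.0
        assert rec.rpe_series[-1][1] == 20.0
        assert rec.stages[-1][1].grade == pytest.approx(0.10)

    def test_submaximal_when_protocol_ceiling_too_low(self):
        model = sim.PhysiologyModel(
            hr_rest=60, hr_max=190, max_mets=18.0,
            hr_noise_sd=0.0, rpe_noise_sd=0.0, seed=0,
        )
        rec = sim.simulate_gxt(model)  # Balke tops out below 18 METs
        assert rec.submaximal
        assert rec.hr_series[-1][1] < 190.0

    def test_noise_free_locate_closes_the_loop(self):
        model = sim.PhysiologyModel(
            hr_rest=60, hr_max=180, max_mets=13.0,
            hr_noise_sd=0.0, rpe_noise_sd=0.0, seed=0,
        )
        rec = sim.simulate_gxt(model)
        hr_step = float(np.max(np.diff([h for _, h in rec.hr_series])))
        for f in (0.6, 0.7, 0.8):
            t = tr.locate_target(rec, f)
            # the located stage's response brackets the THR within one stage
            hr_at_stage = model.curve.hr_of_mets(min(t.gxt_mets, model.max_mets))
            hr_at_stage = min(hr_at_stage, model.hr_max)
            assert t.thr - 1e-9 <= hr_at_stage <= t.thr + hr_step + 1e-9

    def test_stage_end_noise_has_configured_sd(self):
        # mid-test stage far from both clipping bounds, 200 replicates
        models = [
            sim.PhysiologyModel(
                hr_rest=60, hr_max=180, max_mets=13.0,
                hr_noise_sd=3.0, rpe_noise_sd=0.0, seed=k,
            )
            for k in range(200)
        ]
        hrs = [dict(sim.simulate_gxt(m).hr_series)[480.0] for m in models]
        assert np.std(hrs) == pytest.approx(3.0, abs=0.5)

    def test_seeded_determinism(self):
        model = sim.make_cohort(1, seed=11)[0]
        assert sim.simulate_gxt(model) == sim.simulate_gxt(model)


class TestSimulateBout:
    @staticmethod
    def _model_and_matched_fraction(kappa=0.72, noise=0.0):
        """A subject and an HRR fraction whose THR falls exactly on a
        stage-end response, so the noise-free loop closes exactly."""
        model = sim.PhysiologyModel(
            hr_rest=60, hr_max=180, max_mets=13.0, true_kappa=kappa,
            hr_noise_sd=noise, rpe_noise_sd=noise, seed=5,
        )
        rec = sim.simulate_gxt(model)
        # stage-end HR of the 8%-grade stage
        stage_mets = quiet_mets(mb.Workload(80.4, 0.08))
        thr = model.curve.hr_of_mets(stage_mets)
        fraction = (thr - model.hr_rest) / (model.hr_max - model.hr_rest)
        return model, rec, fraction

    def test_matched_factor_zero_noise_hits_thr_exactly(self):
        model, rec, f = self._model_and_matched_fraction()
        target = tr.locate_target(rec, f)
        rx = tr.translate(target, 0.72, record=rec)
        log = sim.simulate_bout(model, rx)
        s = gs.summarize_bout(log)
        assert s.achieved_hr == pytest.approx(target.thr, abs=1e-9)
        assert s.achieved_rpe == pytest.approx(target.gxt_rpe, abs=1e-9)

    def test_kappa_one_means_no_drift(self):
        model, rec, f = self._model_and_matched_fraction(kappa=1.0)
        target = tr.locate_target(rec, f)
        rx = tr.translate(target, 1.0, record=rec)
        log = sim.simulate_bout(model, rx)
        # sustained response equals the GXT stage response: no drift
        assert gs.summarize_bout(log).achieved_hr == pytest.approx(
            model.curve.hr_of_mets(target.gxt_mets), abs=1e-9
        )

    def test_untranslated_prescription_overshoots(self):
        model, rec, f = self._model_and_matched_fraction(kappa=0.72)
        target = tr.locate_target(rec, f)
        rx = tr.translate(target, 1.0, record=rec)  # no translation
        log = sim.simulate_bout(model, rx)
        assert gs.summarize_bout(log).achieved_hr > target.thr

    def test_supramaximal_demand_warns_and_clips(self):
        model, rec, _ = self._model_and_matched_fraction(kappa=0.6)
        target = tr.locate_target(rec, 0.9)
        rx = tr.translate(target, 1.0, record=rec)
        with pytest.warns(SupramaximalWarning):
            log = sim.simulate_bout(model, rx)
        assert gs.summarize_bout(log).achieved_hr == model.hr_max

    def test_sample_grid_is_five_minutes(self):
        model, rec, f = self._model_and_matched_fraction()
        rx = tr.translate(tr.locate_target(rec, f), 0.72, record=rec)
        log = sim.simulate_bout(model, rx)
        assert [s[0] for s in log.samples] == [300.0 * k for k in range(1, 7)]


class TestKappaRecovery:
    @staticmethod
    def _run(kappa, noise, seed=9):
        model = sim.PhysiologyModel(
            hr_rest=65, hr_max=185, max_mets=12.5, true_kappa=kappa,
            hr_noise_sd=noise, rpe_noise_sd=0.0, seed=seed,
        )
        rec, results = sim.run_subject(model, factor=0.72)
        return sim.recover_kappa(rec, [r["log"] for r in results.values()])

    def test_noise_free_inversion_is_exact(self):
        assert self._run(0.72, 0.0).kappa == pytest.approx(0.72, abs=1e-6)

    def test_kappa_one_identity(self):
        assert self._run(1.0, 0.0).kappa == pytest.approx(1.0, abs=1e-6)

    def test_unrecoverable_bouts_counted(self):
        model = sim.PhysiologyModel(
            hr_rest=65, hr_max=185, max_mets=12.5,
            hr_noise_sd=0.0, rpe_noise_sd=0.0, seed=9,
        )
        rec, results = sim.run_subject(model)
        good = [r["log"] for r in results.values()]
        # a fabricated bout resting below the GXT HR range
        bad = gs.TrainingBoutLog(
            subject=model.subject(),
            prescription=good[0].prescription,
            samples=tuple((300.0 * k, 40.0, 6.0) for k in range(1, 7)),
        )
        with pytest.raises(ValueError):
            sim.recover_kappa(rec, [bad])


class TestExperiment:
    def test_seeded_determinism_of_full_pipeline(self):
        a = sim.simulate_experiment(5, seed=21)
        b = sim.simulate_experiment(5, seed=21)
        assert a.equals(b)

    def test_row_per_subject_and_intensity(self):
        df = sim.simulate_experiment(4, seed=2)
        assert len(df) == 12
        assert set(df["intensity"]) == {0.6, 0.7, 0.8}

    def test_zero_noise_closed_loop_across_cohort(self):
        cohort = sim.make_cohort(10, seed=13, hr_noise_sd=0.0, rpe_noise_sd=0.0)
        for model in cohort:
            rec, results = sim.run_subject(model)
            hr_step = float(np.max(np.diff([h for _, h in rec.hr_series])))
            rpe_step = float(np.max(np.diff([r for _, r in rec.rpe_series])))
            for f, r in results.items():
                d_hr = r["summary"].achieved_hr - r["prescription"].predicted_hr
                d_rpe = r["summary"].achieved_rpe - r["prescription"].predicted_rpe
                assert -1e-9 <= d_hr <= hr_step + 1e-9
                assert -1e-9 <= d_rpe <= rpe_step + 1e-9
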
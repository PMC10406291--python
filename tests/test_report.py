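import json

import numpy as np
import pytest

from taskfmri_qc import motion_qc, pipeline, report, synthetic
from taskfmri_qc.errors import ValidationError
from taskfmri_qc.synthetic import MissingPattern, PhantomSpec, Spike, SynthSpec
from taskfmri_qc.types import QCDecision

from conftest import make_events

SMALL_PHANTOM = PhantomSpec(shape=(12, 12, 6), brain_axes_vox=(4.5, 5.5, 2.5))


def _record(run_id="sub-001", seed=1, **spec_kwargs):
    spec = SynthSpec(seed=seed, run_id=run_id, n_frames=60,
                     phantom=SMALL_PHANTOM, **spec_kwargs)
    events, motion, image = synthetic.synth_run(spec)
    return pipeline.process_run(events, motion, image)


class TestQCDecision:
    def test_excluded_iff_any_criterion_fails(self):
        d = QCDecision("r", "pass", "pass", "fail", "pass")
        assert d.excluded
        d2 = QCDecision("r", "pass", "pass", "pass", "needs_review")
        assert not d2.excluded

    def test_criterion_d_fail_requires_note(self):
        with pytest.raises(ValidationError):
            QCDecision("r", "pass", "pass", "pass", "fail_by_override")
        d = QCDecision("r", "pass", "pass", "pass", "fail_by_override",
                       override_note="wrong acquisition protocol")
        assert d.excluded

    def test_needs_review_without_override_does_not_exclude(self):
        rec = _record()
        d = report.decide(rec, metadata_deviant=True)
        assert d.criterion_d == "needs_review" and not d.excluded

    def test_override_models_human_exclusion(self):
        rec = _record()
        d = report.decide(rec, override=("fail_by_override", "distorted images"))
        assert d.excluded and d.override_note == "distorted images"


class TestMotionFigure:
    def test_zero_censored_annotation(self, tmp_path):
        rec = _record(seed=2)
        png = report.motion_figure(rec.motion, rec.censor, rec.events,
                                   out_path=str(tmp_path / "m.png"))
        assert png.startswith(b"\x89PNG")
        assert rec.censor.n_censored == 0

    def test_spiked_run_marks_exactly_one_frame(self):
        rec = _record(seed=3, drift_mm=0.0, spikes=[Spike(frame=30, magnitude_mm=1.5)])
        assert rec.censor.censored_frame_indices == [30]
        png = report.motion_figure(rec.motion, rec.censor, rec.events)
        assert len(png) > 1000

    def test_run_mismatch_rejected(self):
        rec_a = _record("sub-001", seed=4)
        rec_b = _record("sub-002", seed=5)
        with pytest.raises(ValidationError, match="mismatch"):
            report.motion_figure(rec_a.motion, rec_b.censor)


class TestBehaviorFigure:
    def test_figure_renders_with_missing_block(self):
        rec = _record(seed=6, missing_pattern=MissingPattern(kind="block", k=5,
                                                             start_index=12))
        png = report.behavior_figure([rec.events], [rec.behavior])
        assert png.startswith(b"\x89PNG")

    def test_misaligned_lists_rejected(self):
        rec_a = _record("sub-001", seed=7)
        rec_b = _record("sub-002", seed=8)
        with pytest.raises(ValidationError):
            report.behavior_figure([rec_a.events], [rec_b.behavior])
        with pytest.raises(ValidationError):
            report.behavior_figure([], [])


class TestBuildReports:
    def _dataset(self):
        specs = [
            SynthSpec(seed=20, run_id="sub-001", n_frames=60, phantom=SMALL_PHANTOM),
            SynthSpec(seed=21, run_id="sub-002", n_frames=60, phantom=SMALL_PHANTOM),
            SynthSpec(seed=22, run_id="sub-003", n_frames=60, phantom=SMALL_PHANTOM,
                      missing_pattern=MissingPattern(kind="block", k=6, start_index=30)),
        ]
        artifacts = [synthetic.synth_run(sp) for sp in specs]
        return pipeline.process_dataset(artifacts)

    def test_end_to_end_json_names_the_failing_run(self, tmp_path):
        records, mismatches, decisions = self._dataset()
        paths = report.build_reports(records, decisions, str(tmp_path),
                                     mismatches=mismatches)
        with open(paths["decisions"]) as fh:
            payload = json.load(fh)
        excluded = [r for r in payload["runs"] if r["decision"]["excluded"]]
        assert len(excluded) == 1
        assert excluded[0]["run_id"] == "sub-003"
        assert excluded[0]["decision"]["criterion_c"] == "fail"

    def test_rerun_is_byte_identical(self, tmp_path):
        records, mismatches, decisions = self._dataset()
        p1 = report.build_reports(records, decisions, str(tmp_path / "a"),
                                  mismatches=mismatches)
        p2 = report.build_reports(records, decisions, str(tmp_path / "b"),
                                  mismatches=mismatches)
        with open(p1["decisions"], "rb") as f1, open(p2["decisions"], "rb") as f2:
            assert f1.read() == f2.read()

    def test_excluded_rederivable_from_json_alone(self, tmp_path):
        records, mismatches, decisions = self._dataset()
        paths = report.build_reports(records, decisions, str(tmp_path),
                                     mismatches=mismatches)
        with open(paths["decisions"]) as fh:
            payload = json.load(fh)
        for run in payload["runs"]:
            d = run["decision"]
            rederived = (
                d["criterion_a"] == "fail" or d["criterion_b"] == "fail"
                or d["criterion_c"] == "fail" or d["criterion_d"] == "fail_by_override"
            )
            assert rederived == d["excluded"]

    def test_figure_numbers_match_json_record(self, tmp_path):
        records, mismatches, decisions = self._dataset()
        paths = report.build_reports(records, decisions, str(tmp_path),
                                     mismatches=mismatches)
        with open(paths["decisions"]) as fh:
            payload = json.load(fh)
        by_id = {r["run_id"]: r for r in payload["runs"]}
        for rec in records:
            assert by_id[rec.run_id]["motion"]["n_censored"] == rec.censor.n_censored
            assert by_id[rec.run_id]["behavior"]["n_responses_total"] == \
                rec.behavior.n_responses_total

    def test_missing_decision_rejected(self, tmp_path):
        records, _, decisions = self._dataset()
        with pytest.raises(ValidationError, match="sub-003"):
            report.build_reports(records, decisions[:2], str(tmp_path))


class TestExclusionSummary:
    def test_lists_runs_and_criteria(self):
        decisions = [
            QCDecision("sub-001", "pass", "pass", "pass", "pass"),
            QCDecision("sub-002", "fail", "pass", "fail", "pass"),
        ]
        text = report.exclusion_summary(decisions)
        assert "sub-002" in text and "A, C" in text and "sub-001" not in text

    def test_clean_dataset_message(self):
        decisions = [QCDecision("sub-001", "pass", "pass", "pass", "pass")]
        assert report.exclusion_summary(decisions) == "no runs excluded"


class TestPipeline:
    def test_overlap_counts_partition_censored_frames(self):
        rec = _record(seed=30, drift_mm=0.0,
                      spikes=[Spike(frame=f, magnitude_mm=1.5) for f in (5, 25, 45)])
        assert rec.overlap is not None
        assert (rec.overlap.n_censored_in_trials
                + rec.overlap.n_censored_outside_trials) == rec.censor.n_censored

    def test_frame_times_require_tr(self, motion_factory):
        cfg = pipeline.QCConfig()
        with pytest.raises(ValidationError, match="RepetitionTime"):
            pipeline.frame_times_for(motion_factory(10), None, cfg)
        times = pipeline.frame_times_for(motion_factory(10), None,
                                         pipeline.QCConfig(tr_s=2.0))
        np.testing.assert_allclose(times, np.arange(10) * 2.0)
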
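import numpy as np
import pytest

from retroprobe import (
    DesignSpec,
    GenerativeParams,
    SessionData,
    TrialRecord,
    exclude_participants,
    label_responses,
    read_trials,
    response_table,
    simulate_cohort,
    write_trials,
)
from retroprobe.data_model import CSV_COLUMNS, SchemaError, ValidationError


def make_trial(**overrides) -> TrialRecord:
    base = dict(
        subject_id="S01",
        experiment="E1",
        block=1,
        trial=1,
        condition="cued_first",
        order_cued=False,
        item_angles=(10.0, 100.0, 190.0, 280.0),
        cued_item=2,
        probe1_item=2,
        probe2_item=4,
        response1_deg=12.5,
        response2_deg=281.0,
    )
    base.update(overrides)
    rec = TrialRecord(**base)
    rec.validate()
    return rec


class TestValidation:
    def test_probe_items_must_differ(self):
        with pytest.raises(ValidationError, match="probe1_item"):
            make_trial(probe2_item=2)

    def test_cued_first_requires_cued_probe_first(self):
        with pytest.raises(ValidationError, match="cued_first"):
            make_trial(probe1_item=3, probe2_item=4)

    def test_neutral_has_no_cued_item(self):
        with pytest.raises(ValidationError, match="neutral"):
            make_trial(condition="neutral", cued_item=1)
        make_trial(condition="neutral", cued_item=None)  # valid

    def test_angle_range(self):
        with pytest.raises(ValidationError):
            make_trial(item_angles=(0.0, 360.0, 10.0, 20.0))
        with pytest.raises(ValidationError):
            make_trial(response1_deg=-1.0)

    def test_session_requires_single_subject(self):
        a = make_trial()
        b = make_trial(subject_id="S02")
        with pytest.raises(ValidationError):
            SessionData(records=[a, b])


class TestLabelResponses:
    @pytest.mark.parametrize(
        "condition, roles",
        [
            ("cued_first", ("cued", "uncued")),
            ("cued_second", ("uncued", "cued")),
            ("neutral", ("neutral", "neutral")),
        ],
    )
    def test_role_assignment(self, condition, roles):
        kwargs = {"condition": condition}
        if condition == "neutral":
            kwargs["cued_item"] = None
        elif condition == "cued_second":
            kwargs.update(cued_item=4, probe1_item=2, probe2_item=4)
        r1, r2 = label_responses(make_trial(**kwargs))
        assert (r1.role, r2.role) == roles
        assert (r1.response_index, r2.response_index) == (1, 2)


class TestCsvRoundTrip:
    def test_simulated_cohort_round_trips(self, tmp_path, small_cohort):
        path = tmp_path / "trials.csv"
        write_trials(small_cohort, path)
        back = read_trials(path)
        assert len(back) == len(small_cohort)
        for orig, re_read in zip(small_cohort, back):
            assert len(orig) == len(re_read)
            for a, b in zip(orig.records, re_read.records):
                assert a.subject_id == b.subject_id
                assert a.condition == b.condition
                assert (a.cued_item, a.probe1_item, a.probe2_item) == (
                    b.cued_item,
                    b.probe1_item,
                    b.probe2_item,
                )
                np.testing.assert_allclose(a.item_angles, b.item_angles, atol=1e-6)
                assert a.response1_deg == pytest.approx(b.response1_deg, abs=1e-6)

    def test_missing_response_round_trips_as_missing(self, tmp_path):
        s = SessionData(records=[make_trial(response2_deg=None)])
        path = tmp_path / "t.csv"
        write_trials([s], path)
        (back,) = read_trials(path)
        assert back.records[0].response2_deg is None
        assert back.records[0].response1_deg == pytest.approx(12.5)

    def test_two_row_csv(self, tmp_path):
        s = SessionData(records=[make_trial(), make_trial(trial=2)])
        path = tmp_path / "t.csv"
        write_trials([s], path)
        sessions = read_trials(path)
        assert len(sessions) == 1 and len(sessions[0]) == 2

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        write_trials([], path)
        assert path.read_text().strip() == ",".join(CSV_COLUMNS)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,experiment\nS01,E1\n")
        with pytest.raises(SchemaError, match="block"):
            read_trials(path)

    def test_invalid_row_named_in_error(self, tmp_path):
        s = SessionData(records=[make_trial()])
        path = tmp_path / "t.csv"
        write_trials([s], path)
        text = path.read_text().replace("12.500000", "400.0")
        path.write_text(text)
        with pytest.raises(ValidationError, match="row 2"):
            read_trials(path)

    def test_extra_column_warns(self, tmp_path):
        s = SessionData(records=[make_trial()])
        path = tmp_path / "t.csv"
        write_trials([s], path)
        lines = path.read_text().splitlines()
        lines[0] += ",bogus"
        lines[1] += ",1"
        path.write_text("\n".join(lines))
        with pytest.warns(UserWarning, match="bogus"):
            read_trials(path)


class TestExclusion:
    @staticmethod
    def _uniform_responder(rng, n_trials=240):
        records = []
        for t in range(n_trials):
            records.append(
                make_trial(
                    trial=t + 1,
                    item_angles=tuple(rng.uniform(0, 360, 4)),
                    response1_deg=float(rng.uniform(0, 360)),
                    response2_deg=float(rng.uniform(0, 360)),
                )
            )
        return SessionData(records=records)

    @staticmethod
    def _perfect_responder(rng, n_trials=30):
        records = []
        for t in range(n_trials):
            items = tuple(rng.uniform(0, 360, 4))
            records.append(
                make_trial(
                    trial=t + 1,
                    item_angles=items,
                    response1_deg=items[1],
                    response2_deg=items[3],
                )
            )
        return SessionData(records=records)

    def test_uniform_responder_excluded_perfect_retained(self, rng):
        uniform = self._uniform_responder(rng)
        perfect = SessionData(
            records=[r.__class__(**{**r.__dict__, "subject_id": "S02"}) for r in
                     self._perfect_responder(rng).records]
        )
        retained, report = exclude_participants([uniform, perfect])
        assert [s.subject_id for s in retained] == ["S02"]
        assert report.set_index("subject")["excluded"].to_dict() == {"S01": True, "S02": False}

    def test_good_simulated_cohort_has_no_exclusions(self):
        cohort = simulate_cohort(
            DesignSpec.e1(), GenerativeParams.flat(p_mem=0.7, kappa=10.0), 6, seed=3
        )
        retained, report = exclude_participants(cohort)
        assert len(retained) == 6
        assert not report["excluded"].any()

    def test_decision_invariant_to_trial_order(self, rng):
        s = self._uniform_responder(rng)
        reversed_s = SessionData(records=list(reversed(s.records)))
        _, rep1 = exclude_participants([s])
        _, rep2 = exclude_participants([reversed_s])
        assert rep1["p"].iloc[0] == pytest.approx(rep2["p"].iloc[0])

    def test_too_few_responses_raises(self):
        s = SessionData(records=[make_trial(trial=t + 1) for t in range(3)])
        with pytest.raises(ValueError, match="S01"):
            exclude_participants([s])


class TestResponseTable:
    def test_delta_is_other_probed_item_relative_to_target(self):
        # probe1 = item2 (100 deg), probe2 = item4 (280 deg)
        tab = response_table([SessionData(records=[make_trial()])])
        r1 = tab[tab.response_index == 1].iloc[0]
        assert np.rad2deg(r1["delta"]) == pytest.approx(180.0, abs=1e-9)
        r2 = tab[tab.response_index == 2].iloc[0]
        assert np.rad2deg(r2["delta"]) == pytest.approx(180.0, abs=1e-9)
        # response1 12.5 deg vs target 100 deg -> -87.5 deg (clockwise)
        assert np.rad2deg(r1["error"]) == pytest.approx(-87.5, abs=1e-9)

    def test_missing_responses_dropped_listwise(self):
        tab = response_table([SessionData(records=[make_trial(response2_deg=None)])])
        assert list(tab["response_index"]) == [1]
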
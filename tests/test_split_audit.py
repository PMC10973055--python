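import random

import pytest

from splitaudit import split_audit as sa
from splitaudit.config import SetLabel, SplitAssignment, Surgery
from splitaudit.synthetic import dense_spec, generate_dataset, plant_unrepresented
from splitaudit.workflow_stats import make_transition


def make_key(kind, payload):
    return sa.AttributeKey(sa.AttributeKind(kind), payload)


class TestFindUnrepresented:
    def split(self):
        return SplitAssignment.from_lists(train=["a"], val=["b"], test=["c"])

    def test_fully_covered_attribute_not_flagged(self):
        counts = {
            make_key("phase", "P1"): {
                SetLabel.TRAIN: 5, SetLabel.VAL: 2, SetLabel.TEST: 1
            }
        }
        assert sa.find_unrepresented(counts, self.split()) == {}

    def test_train_only_combination_flagged_for_val_and_test(self):
        key = make_key("combination", ("A", "B"))
        counts = {key: {SetLabel.TRAIN: 3}}
        flags = sa.find_unrepresented(counts, self.split())
        assert flags == {key: frozenset({SetLabel.VAL, SetLabel.TEST})}

    def test_empty_val_not_audited(self):
        key = make_key("phase", "P1")
        split = SplitAssignment.from_lists(train=["a"], test=["c"])
        flags = sa.find_unrepresented({key: {SetLabel.TRAIN: 1}}, split)
        assert flags == {key: frozenset({SetLabel.TEST})}

    def test_globally_absent_attribute_never_flagged(self):
        key = make_key("phase", "P9")
        assert sa.find_unrepresented({key: {}}, self.split()) == {}


class TestAuditReport:
    def test_toy_audit_summary(self, toy_surgeries, toy_config):
        report = sa.audit(toy_surgeries, toy_config.split, toy_config)
        summary = report.summary()
        # empty VAL is excluded entirely
        assert set(summary["phase"]) == {SetLabel.TRAIN, SetLabel.TEST}
        # matrix cells equal flag-set cardinalities
        for row, cells in summary.items():
            for s, v in cells.items():
                expected = sum(
                    1
                    for key, absent in report.absent_in.items()
                    if s in absent and sa._summary_row(key) == row
                )
                assert v == expected

    def test_no_flags_means_zero_matrix(self, dense_dataset):
        ds = dense_dataset
        report = sa.audit(ds.surgeries, ds.split, ds.config)
        for cells in report.summary().values():
            assert all(v == 0 for v in cells.values())

    def test_designed_test_only_combination(self, toy_config):
        surgeries = [
            Surgery("s1", (0,), phases=("P1",), instruments=((1, 0, 0),)),
            Surgery("s2", (0,), phases=("P1",), instruments=((0, 1, 0),)),
            Surgery("s3", (0,), phases=("P1",), instruments=((1, 1, 0),)),
        ]
        report = sa.audit(surgeries, toy_config.split, toy_config)
        key = make_key("combination", ("A", "B"))
        assert report.absent_in[key] == frozenset({SetLabel.TRAIN})
        assert report.summary()["combination"][SetLabel.TRAIN] == 1

    def test_phase_only_dataset_reports_instruments_na(self, toy_config):
        surgeries = [
            Surgery(sid, (0, 1), phases=("P1", "P2")) for sid in ("s1", "s2", "s3")
        ]
        report = sa.audit(surgeries, toy_config.split, toy_config)
        summary = report.summary()
        assert all(v is None for v in summary["instrument"].values())
        assert all(v is None for v in summary["combination"].values())
        assert all(v == 0 for v in summary["phase"].values())

    def test_sentinel_transitions_in_separate_row(self, toy_config):
        surgeries = [
            Surgery("s1", (0, 1), phases=("P1", "P2")),
            Surgery("s2", (0, 1), phases=("P1", "P2")),
            Surgery("s3", (0, 1), phases=("P2", "P3")),  # test starts in P2
        ]
        report = sa.audit(surgeries, toy_config.split, toy_config)
        summary = report.summary()
        start_p2 = make_key(
            "transition", make_transition("START", "P2", toy_config)
        )
        assert SetLabel.TRAIN in report.absent_in[start_p2]
        assert summary["transition_sentinel"][SetLabel.TRAIN] >= 1

    def test_json_roundtrip(self, toy_surgeries, toy_config, tmp_path):
        report = sa.audit(toy_surgeries, toy_config.split, toy_config)
        path = tmp_path / "report.json"
        report.to_json(path)
        restored = sa.AuditReport.from_json(path)
        assert restored.to_dict() == report.to_dict()
        assert restored.absent_in == report.absent_in


class TestPerSetTotals:
    def test_single_surgery(self, toy_config):
        s = Surgery("s1", tuple(range(10)), phases=("P1",) * 10)
        totals = sa.per_set_totals([s], toy_config.split)
        assert totals[SetLabel.TRAIN] == sa.SetTotals(1, 10, 10.0)

    def test_empty_val(self, toy_surgeries, toy_config):
        totals = sa.per_set_totals(toy_surgeries, toy_config.split)
        assert totals[SetLabel.VAL] == sa.SetTotals(0, 0, None)


class TestReassign:
    def test_empty_moves_identity(self, dense_dataset):
        ds = dense_dataset
        result = sa.reassign(ds.split, [], surgeries=ds.surgeries, config=ds.config)
        assert result.split.assignment == ds.split.assignment
        assert result.newly_covered == [] and result.newly_lost == []

    def test_involution(self, dense_dataset):
        ds = dense_dataset
        sid = ds.split.members(SetLabel.TRAIN)[0]
        once = sa.reassign(ds.split, [(sid, SetLabel.TEST)])
        back = sa.reassign(once.split, [(sid, SetLabel.TRAIN)])
        assert back.split.assignment == ds.split.assignment

    def test_original_split_untouched(self, dense_dataset):
        ds = dense_dataset
        before = dict(ds.split.assignment)
        sid = ds.split.members(SetLabel.TRAIN)[0]
        sa.reassign(ds.split, [(sid, SetLabel.TEST)])
        assert ds.split.assignment == before

    def test_unknown_surgery_rejected(self, dense_dataset):
        with pytest.raises(KeyError, match="nope"):
            sa.reassign(dense_dataset.split, [("nope", SetLabel.TEST)])

    def test_noop_move_warns(self, dense_dataset):
        ds = dense_dataset
        sid = ds.split.members(SetLabel.TRAIN)[0]
        result = sa.reassign(ds.split, [(sid, SetLabel.TRAIN)])
        assert any("no-op" in w for w in result.warnings)
        assert result.split.assignment == ds.split.assignment

    def test_diff_equals_de_novo_recomputation(self):
        ds = generate_dataset(
            plant_unrepresented(dense_spec(seed=21), "combination", (3, 4), "test")
        )
        donor = ds.split.members(SetLabel.TRAIN)[0]
        result = sa.reassign(
            ds.split, [(donor, SetLabel.TEST)], surgeries=ds.surgeries, config=ds.config
        )
        de_novo = sa.audit(ds.surgeries, result.split, ds.config)
        assert result.report_after.to_dict() == de_novo.to_dict()
        # the donor surgery carries the planted combination into TEST
        key = make_key("combination", ("Tool04", "Tool05"))
        assert (key, SetLabel.TEST) in result.newly_covered


class TestGreedyImprove:
    def one_swap_fixture(self):
        """Combination A+B lives only in TRAIN (s1, s2); one swap fixes it."""
        base = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        surgeries = [
            Surgery("s1", tuple(range(4)), phases=("P1", "P1", "P2", "P2"),
                    instruments=tuple(base) + ((1, 1, 0),)),
            Surgery("s2", tuple(range(4)), phases=("P1", "P1", "P2", "P2"),
                    instruments=tuple(base) + ((1, 1, 0),)),
            Surgery("s3", tuple(range(3)), phases=("P1", "P1", "P2"),
                    instruments=tuple(base)),
            Surgery("s4", tuple(range(3)), phases=("P1", "P1", "P2"),
                    instruments=tuple(base)),
        ]
        split = SplitAssignment.from_lists(train=["s1", "s2"], test=["s3", "s4"])
        return surgeries, split

    def test_zero_objective_returns_input(self, dense_dataset):
        ds = dense_dataset
        result = sa.greedy_improve(ds.surgeries, ds.split, ds.config)
        assert result.objective_initial == 0
        assert result.split.assignment == ds.split.assignment
        assert result.trace == []

    def test_one_swap_fixture_solved(self, toy_config):
        surgeries, split = self.one_swap_fixture()
        before = sa.audit(surgeries, split, toy_config)
        assert before.objective() == 1.0
        result = sa.greedy_improve(surgeries, split, toy_config)
        assert result.objective_final == 0
        assert len(result.trace) == 1
        after = sa.audit(surgeries, result.split, toy_config)
        assert after.objective() == 0

    def test_keep_set_sizes(self, toy_config):
        surgeries, split = self.one_swap_fixture()
        result = sa.greedy_improve(surgeries, split, toy_config, keep_set_sizes=True)
        assert result.split.sizes() == split.sizes()

    def test_never_increases_objective(self):
        rng = random.Random(5)
        for trial in range(10):
            seed = rng.randrange(10**6)
            spec = dense_spec(seed=seed, n_surgeries=8, mean_run_length=4.0)
            ds = generate_dataset(spec)
            initial = sa.audit(ds.surgeries, ds.split, ds.config).objective()
            result = sa.greedy_improve(
                ds.surgeries, ds.split, ds.config, max_iter=5,
                seed=rng.randrange(10**6),
            )
            assert result.objective_initial == initial
            assert result.objective_final <= result.objective_initial

    def test_objective_matches_audit(self):
        ds = generate_dataset(
            plant_unrepresented(dense_spec(seed=9), "transition", (4, 2), "train")
        )
        result = sa.greedy_improve(ds.surgeries, ds.split, ds.config, max_iter=0)
        assert result.objective_initial == sa.audit(
            ds.surgeries, ds.split, ds.config
        ).objective()
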
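import csv
import json

import pytest

from splitaudit import instrument_stats, report_viz as rv, split_audit, workflow_stats
from splitaudit.config import SetLabel
from splitaudit.split_audit import AuditReport, audit, summarize_unrepresented
from splitaudit.synthetic import dense_spec, generate_dataset, plant_unrepresented


@pytest.fixture
def aggregates(toy_surgeries, toy_config):
    split = toy_config.split
    return {
        "pc": workflow_stats.aggregate_phase_counts(toy_surgeries, split, toy_config),
        "tc": workflow_stats.aggregate_transition_counts(toy_surgeries, split, toy_config),
        "pic": workflow_stats.per_phase_instrument_counts(toy_surgeries, split, toy_config),
        "ic": instrument_stats.aggregate_instrument_counts(toy_surgeries, split, toy_config),
        "cc": instrument_stats.aggregate_combination_counts(toy_surgeries, split, toy_config),
        "durations": workflow_stats.surgery_durations(toy_surgeries, split),
        "totals": split_audit.per_set_totals(toy_surgeries, split),
    }


class TestPhaseView:
    def test_smoke_renders_nonempty_file(self, aggregates, toy_config, tmp_path):
        out = tmp_path / "phase.svg"
        rv.render_phase_view(
            aggregates["pc"], aggregates["tc"], aggregates["pic"], toy_config, out,
            arc_pies=True,
        )
        assert out.stat().st_size > 0

    def test_nodes_in_conceptual_order(self, aggregates, toy_config):
        model = rv.phase_view_model(
            aggregates["pc"], aggregates["tc"], aggregates["pic"], toy_config
        )
        xs = [n["x"] for n in model["nodes"]]
        assert [n["phase"] for n in model["nodes"]] == list(toy_config.phases)
        assert xs == sorted(xs)

    def test_arc_width_monotone_in_occurrences(self, toy_config):
        from splitaudit.workflow_stats import TransitionCounts, make_transition

        t1 = make_transition("P1", "P2", toy_config)
        t2 = make_transition("P2", "P3", toy_config)
        tc = TransitionCounts({(t1, SetLabel.TRAIN): 2, (t2, SetLabel.TRAIN): 4})
        pc = workflow_stats.PhaseCounts({}, {}, toy_config.phases)
        model = rv.phase_view_model(pc, tc, {}, toy_config)
        widths = {(a["source"], a["target"]): a["width"] for a in model["arcs"]}
        assert widths[("P2", "P3")] > widths[("P1", "P2")]

    def test_forward_up_backward_down_sentinels_at_edges(self, aggregates, toy_config):
        model = rv.phase_view_model(
            aggregates["pc"], aggregates["tc"], aggregates["pic"], toy_config
        )
        for arc in model["arcs"]:
            if arc["direction"] == "forward":
                assert arc["y_sign"] == 1
            elif arc["direction"] == "backward":
                assert arc["y_sign"] == -1
            if arc["source"] == "START":
                assert arc["x0"] == model["x_start"]
            if arc["target"] == "END":
                assert arc["x1"] == model["x_end"]

    def test_train_only_transition_has_all_red_pie(self, aggregates, toy_config):
        model = rv.phase_view_model(
            aggregates["pc"], aggregates["tc"], aggregates["pic"], toy_config
        )
        arc = next(
            a for a in model["arcs"] if (a["source"], a["target"]) == ("P3", "P2")
        )  # only surgery s2 (train) goes backward P3 -> P2
        assert arc["pie"][SetLabel.TRAIN] == 1.0
        assert arc["pie"][SetLabel.TEST] == 0.0

    def test_numbers_taken_verbatim(self, aggregates, toy_config):
        model = rv.phase_view_model(
            aggregates["pc"], aggregates["tc"], aggregates["pic"], toy_config
        )
        pc = aggregates["pc"]
        for node in model["nodes"]:
            assert node["total_frames"] == pc.total(node["phase"])
            assert node["surgery_count"] == pc.surgery_count(node["phase"])
            for s in SetLabel:
                assert node["counts"][s] == pc.frame_count(node["phase"], s)

    def test_empty_dataset_rejected(self, toy_config, tmp_path):
        pc = workflow_stats.PhaseCounts({}, {}, ())
        tc = workflow_stats.TransitionCounts({})
        with pytest.raises(ValueError, match="empty"):
            rv.render_phase_view(pc, tc, {}, toy_config, tmp_path / "x.svg")


class TestInstrumentView:
    def test_smoke(self, aggregates, toy_config, tmp_path):
        out = tmp_path / "instruments.png"
        rv.render_instrument_view(
            aggregates["ic"], aggregates["cc"], toy_config, out
        )
        assert out.stat().st_size > 0

    def test_zero_val_combination_pie_has_no_green(self, aggregates, toy_config):
        model = rv.instrument_view_model(
            aggregates["ic"], aggregates["cc"], toy_config
        )
        for combo in model["combos"]:
            if combo["counts"][SetLabel.VAL] == 0:
                assert combo["pie"][SetLabel.VAL] == 0.0

    def test_layout_reproducible_for_fixed_seed(self, aggregates, toy_config):
        kwargs = dict(layout_seed=3)
        a = rv.instrument_view_model(aggregates["ic"], aggregates["cc"], toy_config, **kwargs)
        b = rv.instrument_view_model(aggregates["ic"], aggregates["cc"], toy_config, **kwargs)
        assert [c["pos"] for c in a["combos"]] == [c["pos"] for c in b["combos"]]

    def test_normalized_bars_scaled_per_instrument(self, aggregates, toy_config):
        model = rv.instrument_view_model(
            aggregates["ic"], aggregates["cc"], toy_config, normalize_bars=True
        )
        for bar in model["bars"]:
            if any(bar["counts"].values()):
                assert max(bar["scaled"].values()) == pytest.approx(1.0)

    def test_idle_bar_present(self, aggregates, toy_config):
        model = rv.instrument_view_model(aggregates["ic"], aggregates["cc"], toy_config)
        assert model["idle"]["counts"][SetLabel.TRAIN] == aggregates["ic"].idle[SetLabel.TRAIN]


class TestSupplementaryView:
    def test_smoke(self, aggregates, toy_config, tmp_path):
        out = tmp_path / "summary.svg"
        rv.render_supplementary(
            aggregates["totals"], aggregates["durations"], toy_config.split, out
        )
        assert out.stat().st_size > 0

    def test_mean_line_equals_computed_mean(self, aggregates, toy_config):
        model = rv.supplementary_model(
            aggregates["totals"], aggregates["durations"], toy_config.split
        )
        durs = aggregates["durations"]
        for set_name, panel in model["panels"].items():
            vals = [e["duration"] for e in panel["surgeries"]]
            assert panel["mean"] == pytest.approx(sum(vals) / len(vals))
            assert panel["mean"] == durs.means[SetLabel(set_name)]

    def test_empty_val_panel_omitted(self, aggregates, toy_config):
        model = rv.supplementary_model(
            aggregates["totals"], aggregates["durations"], toy_config.split
        )
        assert "val" not in model["panels"]
        assert model["sets"] == ["train", "test"]


class TestWriteReport:
    @pytest.fixture
    def report(self):
        ds = generate_dataset(
            plant_unrepresented(dense_spec(seed=2), "combination", (3, 4), "val")
        )
        return audit(ds.surgeries, ds.split, ds.config)

    def test_json_roundtrip_lossless(self, report, tmp_path):
        path = rv.write_report(report, tmp_path / "r.json")
        restored = AuditReport.from_json(path)
        assert restored.to_dict() == report.to_dict()

    def test_markdown_contains_summary_matrix(self, report, tmp_path):
        path = rv.write_report(report, tmp_path / "r.md")
        text = path.read_text()
        assert "absent_in_train" in text and "absent_in_val" in text
        summary = summarize_unrepresented(report)
        row = summary["combination"]
        cells = f"| combination | {row[SetLabel.TRAIN]} | {row[SetLabel.VAL]} | {row[SetLabel.TEST]} |"
        assert cells in text

    def test_csv_parseable_and_complete(self, report, tmp_path):
        path = rv.write_report(report, tmp_path / "r.csv")
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(report.attributes)
        flagged = [r for r in rows if r["absent_in"]]
        assert len(flagged) == len(report.absent_in)

    def test_unknown_format_rejected(self, report, tmp_path):
        with pytest.raises(ValueError, match="format"):
            rv.write_report(report, tmp_path / "r.xml", fmt="xml")


class TestFilterSurgeries:
    def test_phase_filter_keeps_matching_frames(self, toy_surgeries, toy_config):
        out = rv.filter_surgeries(toy_surgeries, toy_config, phases=["P2"])
        assert all(set(s.phases) == {"P2"} for s in out)
        total = sum(s.duration for s in out)
        assert total == sum(
            1 for s in toy_surgeries for p in s.phases if p == "P2"
        )

    def test_transition_filter_keeps_whole_surgeries(self, toy_surgeries, toy_config):
        out = rv.filter_surgeries(toy_surgeries, toy_config, transition=("P3", "P2"))
        assert [s.surgery_id for s in out] == ["s2"]
        assert out[0].duration == 4  # untouched

    def test_combination_filter_exact_set(self, toy_surgeries, toy_config):
        out = rv.filter_surgeries(toy_surgeries, toy_config, combination=["A", "B"])
        for s in out:
            for vec in s.instruments:
                assert vec == (1, 1, 0)

    def test_instrument_filter(self, toy_surgeries, toy_config):
        out = rv.filter_surgeries(toy_surgeries, toy_config, instrument="C")
        kept = sum(s.duration for s in out)
        want = sum(1 for s in toy_surgeries for v in s.instruments if v[2])
        assert kept == want
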
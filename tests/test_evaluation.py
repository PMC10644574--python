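import pytest

from mapalign.errors import IntegrityError
from mapalign.evaluation import (
    AnnotationSet,
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    correspond_predictions,
    evaluate_matchings,
    infer_annotation,
)
from mapalign.feature_io import Feature, Run
from mapalign.relation_graph import ToleranceConfig


def annotation(entries, runs=("r1", "r2", "r3")):
    return AnnotationSet(run_names=list(runs), analytes=entries)


class TestCorrespondPredictions:
    def test_identical_prediction_maps_one_to_one(self):
        ann = annotation({
            "a1": {"r1": "x1", "r2": "x2", "r3": "x3"},
            "a2": {"r1": "y1", "r2": "y2", "r3": None},
        })
        predicted = [
            {"r1": "x1", "r2": "x2", "r3": "x3"},
            {"r1": "y1", "r2": "y2"},
        ]
        corr = correspond_predictions(predicted, ann)
        assert corr == {"a1": 0, "a2": 1}

    def test_split_analyte_picks_larger_overlap(self):
        ann = annotation(
            {"a1": {f"r{i}": f"x{i}" for i in range(1, 6)}},
            runs=[f"r{i}" for i in range(1, 6)],
        )
        predicted = [
            {"r1": "x1", "r2": "x2", "r3": "x3"},  # 3 shared
            {"r4": "x4", "r5": "x5"},              # 2 shared
        ]
        assert correspond_predictions(predicted, ann) == {"a1": 0}

    def test_zero_overlap_gives_none(self):
        ann = annotation({"a1": {"r1": "x1", "r2": None, "r3": None}})
        assert correspond_predictions([{"r1": "other"}], ann) == {"a1": None}

    def test_tie_prefers_fewer_features(self):
        ann = annotation({"a1": {"r1": "x1", "r2": "x2", "r3": None}})
        predicted = [
            {"r1": "x1", "r2": "q", "r3": "q2"},  # 1 shared, 3 features
            {"r2": "x2"},                          # 1 shared, 1 feature
        ]
        assert correspond_predictions(predicted, ann) == {"a1": 1}


class TestConfusionCounts:
    def test_perfect_prediction_all_tp(self):
        ann = annotation({"a1": {"r1": "x1", "r2": "x2", "r3": "x3"}})
        counts, ok = confusion_counts([{"r1": "x1", "r2": "x2", "r3": "x3"}], ann)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (3, 0, 0, 0)
        assert ok == {"a1": True}

    def test_empty_prediction_fn_plus_tn(self):
        ann = annotation({"a1": {"r1": "x1", "r2": None, "r3": "x3"}})
        counts, ok = confusion_counts([], ann)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (0, 0, 1, 2)
        assert ok == {"a1": False}

    def test_hand_tallied_mixed_cells(self):
        # a1: r1 correct, r2 wrong feature (FP), r3 missing (FN)
        # a2: r1 spurious (FP), r2 correct, r3 both absent (TN)
        ann = annotation({
            "a1": {"r1": "x1", "r2": "x2", "r3": "x3"},
            "a2": {"r1": None, "r2": "y2", "r3": None},
        })
        predicted = [
            {"r1": "x1", "r2": "wrong"},
            {"r1": "spur", "r2": "y2"},
        ]
        counts, ok = confusion_counts(predicted, ann)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (2, 2, 1, 1)
        assert ok == {"a1": False, "a2": False}

    def test_conservation_total_equals_analytes_times_runs(self):
        ann = annotation({
            "a1": {"r1": "x1", "r2": "x2", "r3": None},
            "a2": {"r1": "y1", "r2": None, "r3": "y3"},
            "a3": {"r1": None, "r2": None, "r3": None},
        })
        predicted = [{"r1": "x1"}, {"r3": "y3", "r1": "zz"}]
        counts, _ = confusion_counts(predicted, ann)
        assert counts.total == 3 * 3

    def test_wrong_feature_is_single_fp_not_fp_plus_fn(self):
        ann = annotation({"a1": {"r1": "x1", "r2": "x2", "r3": "x3"}})
        counts, _ = confusion_counts([{"r1": "x1", "r2": "bad", "r3": "x3"}], ann)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (2, 1, 0, 0)
        assert counts.total == 3


class TestComputeMetrics:
    def test_degenerate_all_tn(self):
        report = compute_metrics(ConfusionCounts(0, 0, 10, 0), {"a": True})
        assert report.feature_accuracy == 1.0
        assert report.precision == 0.0 and report.recall == 0.0

    def test_analyte_accuracy_fraction_of_clean_rows(self):
        report = compute_metrics(ConfusionCounts(5, 1, 0, 0), {"a": True, "b": False})
        assert report.analyte_accuracy == 0.5

    def test_f1_is_harmonic_mean(self):
        report = compute_metrics(ConfusionCounts(8, 2, 0, 2), {})
        p, r = 0.8, 0.8
        assert report.f1 == pytest.approx(2 * p * r / (p + r))

    def test_rounding_half_even_to_three_decimals(self):
        report = compute_metrics(ConfusionCounts(9685, 315, 0, 0), {})
        assert report.rounded()["precision"] == 0.968  # 0.9685 rounds half-even


class TestAnnotationSet:
    def test_feature_claimed_twice_rejected(self):
        with pytest.raises(IntegrityError):
            AnnotationSet(
                run_names=["r1"],
                analytes={"a1": {"r1": "x"}, "a2": {"r1": "x"}},
            )

    def test_csv_roundtrip(self, tmp_path):
        ann = annotation({"a1": {"r1": "x1", "r2": None, "r3": "x3"}})
        path = str(tmp_path / "ann.csv")
        ann.to_csv(path)
        back = AnnotationSet.from_csv(path, run_names=["r1", "r2", "r3"])
        assert back.analytes == ann.analytes


class TestInferAnnotation:
    def runs(self, coords):
        return [
            Run(name=name, acquisition_index=i,
                features=[Feature(m, r, a, fid) for (m, r, a, fid) in feats])
            for i, (name, feats) in enumerate(coords.items())
        ]

    def test_identical_candidates_reproduce_annotation(self):
        ann = AnnotationSet(run_names=["r1"], analytes={"a1": {"r1": "x1"}})
        coords = {"a1": {"r1": (100.0, 1.0)}}
        runs = self.runs({"r1": [(100.0, 1.0, 5.0, "c1")]})
        inferred = infer_annotation(runs, ann, coords, ToleranceConfig(0.01, 0.1))
        assert inferred.analytes["a1"]["r1"] == "c1"

    def test_nearer_normalized_candidate_wins(self):
        ann = AnnotationSet(run_names=["r1"], analytes={"a1": {"r1": "x1"}})
        coords = {"a1": {"r1": (100.0, 1.0)}}
        runs = self.runs({
            "r1": [(100.005, 1.0, 5.0, "far"), (100.0, 1.05, 5.0, "near")],
        })
        # normalized distances: (0.5)^2 = 0.25 vs (0.5)^2 = 0.25 in one dim each;
        # use asymmetric offsets so ranking is strict
        runs = self.runs({
            "r1": [(100.005, 1.05, 5.0, "far"), (100.0, 1.05, 5.0, "near")],
        })
        inferred = infer_annotation(runs, ann, coords, ToleranceConfig(0.01, 0.1))
        assert inferred.analytes["a1"]["r1"] == "near"

    def test_no_candidate_within_tolerance_absent(self):
        ann = AnnotationSet(run_names=["r1"], analytes={"a1": {"r1": "x1"}})
        coords = {"a1": {"r1": (100.0, 1.0)}}
        runs = self.runs({"r1": [(100.5, 1.0, 5.0, "c1")]})
        inferred = infer_annotation(runs, ann, coords, ToleranceConfig(0.01, 0.1))
        assert inferred.analytes["a1"]["r1"] is None

    def test_candidate_claimed_once_per_run(self):
        ann = AnnotationSet(
            run_names=["r1"],
            analytes={"a1": {"r1": "x1"}, "a2": {"r1": "x2"}},
        )
        coords = {"a1": {"r1": (100.0, 1.0)}, "a2": {"r1": (100.002, 1.0)}}
        runs = self.runs({"r1": [(100.0, 1.0, 5.0, "only")]})
        inferred = infer_annotation(runs, ann, coords, ToleranceConfig(0.01, 0.1))
        values = [inferred.analytes[a]["r1"] for a in ("a1", "a2")]
        assert values.count("only") == 1


class TestEndToEndPerfect:
    def test_perfect_alignment_scores_all_ones(self):
        from mapalign.pipeline import JobConfig, align_runs
        from mapalign.synthetic import SynthConfig, generate_benchmark

        cfg = SynthConfig(n_runs=3, n_analytes=30, dropout_prob=0.0, decoy_density=0.0,
                          mz_sd=0.0005, rt_sd=0.005, seed=2)
        runs, ann, _ = generate_benchmark(cfg)
        result = align_runs(runs, JobConfig(seed=2))
        report = evaluate_matchings(result.matchings, ann)
        assert report.precision == report.recall == report.f1 == 1.0
        assert report.feature_accuracy == report.analyte_accuracy == 1.0
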
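"""Hold-out splitting, confusion tables, metrics, stratified comparison."""

import numpy as np
import pytest

from slimtriage.evaluation import (
    ConfusionTable,
    build_confusion,
    compute_metrics,
    holdout_split,
    stratified_compare,
)

# Published 2x3 confusion cells for the two methods on the same 2,335-variant
# evaluation set: rows = (ClinVar pathogenic, gnomAD benign), columns =
# (pathogenic, uncertain, benign) verdicts.
MOTIF_METHOD_TABLE = ConfusionTable(((120, 34, 26), (6, 6, 2143)))
EXTERNAL_TABLE = ConfusionTable(((154, 12, 14), (285, 242, 1628)))


class TestSplit:
    def test_stratified_arithmetic(self):
        labels = ["pathogenic"] * 100 + ["benign"] * 1000
        work, ev = holdout_split(list(range(1100)), labels, fraction=0.2, seed=1)
        ev_labels = [labels[i] for i in ev]
        assert ev_labels.count("pathogenic") == 20
        assert ev_labels.count("benign") == 200
        assert sorted(work + ev) == list(range(1100))

    def test_reproducible_from_seed(self):
        labels = ["pathogenic"] * 10 + ["benign"] * 30
        a = holdout_split(list(range(40)), labels, seed=9)
        b = holdout_split(list(range(40)), labels, seed=9)
        assert a == b

    def test_half_split_of_two_plus_two(self):
        labels = ["pathogenic", "pathogenic", "benign", "benign"]
        work, ev = holdout_split(list(range(4)), labels, fraction=0.5, seed=0)
        ev_labels = [labels[i] for i in ev]
        assert ev_labels.count("pathogenic") == 1
        assert ev_labels.count("benign") == 1

    def test_single_class_warns_and_proceeds(self):
        labels = ["benign"] * 10
        with pytest.warns(UserWarning, match="no members"):
            work, ev = holdout_split(list(range(10)), labels, fraction=0.2, seed=0)
        assert len(ev) == 2

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            holdout_split([1], ["benign"], fraction=1.5)


class TestConfusion:
    def test_perfect_classifier_diagonal(self):
        verdicts = {i: "pathogenic" for i in range(5)}
        verdicts.update({i: "benign" for i in range(5, 10)})
        truths = {i: "pathogenic" for i in range(5)}
        truths.update({i: "benign" for i in range(5, 10)})
        t = build_confusion(verdicts, truths)
        assert t.values == ((5, 0, 0), (0, 0, 5))

    def test_all_uncertain_middle_column(self):
        verdicts = {i: "uncertain" for i in range(6)}
        truths = {i: ("pathogenic" if i < 2 else "benign") for i in range(6)}
        t = build_confusion(verdicts, truths)
        assert t.values == ((0, 2, 0), (0, 4, 0))

    def test_published_cells_sum_to_evaluation_set_size(self):
        assert MOTIF_METHOD_TABLE.n_total == 2335
        assert MOTIF_METHOD_TABLE.n_pathogenic == 180
        assert MOTIF_METHOD_TABLE.n_benign == 2155
        assert EXTERNAL_TABLE.n_total == 2335

    def test_missing_verdict_rejected(self):
        with pytest.raises(ValueError, match="no verdict"):
            build_confusion({}, {1: "benign"})


class TestMetrics:
    def test_motif_method_worked_numbers(self):
        r = compute_metrics(MOTIF_METHOD_TABLE)
        assert round(r.accuracy, 2) == 0.97
        assert round(r.weighted_f1, 2) == 0.98
        assert round(r.mcc_by_convention["uncertain-as-benign"], 2) == 0.78

    def test_external_method_worked_numbers(self):
        r = compute_metrics(EXTERNAL_TABLE)
        assert round(r.accuracy, 2) == 0.76
        assert round(r.weighted_f1, 2) == 0.83
        assert r.mcc_by_convention["uncertain-as-pathogenic"] == pytest.approx(
            0.39, abs=0.01
        )

    def test_perfect_table(self):
        r = compute_metrics(ConfusionTable(((7, 0, 0), (0, 0, 13))))
        assert r.accuracy == 1.0
        assert r.weighted_f1 == pytest.approx(1.0)
        assert r.mcc == pytest.approx(1.0)

    def test_counts_reconcile(self):
        r = compute_metrics(MOTIF_METHOD_TABLE)
        assert r.n_pathogenic + r.n_benign == r.n_total == 2335

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionTable(((0, 0, 0), (0, 0, 0))))

    def test_order_independence_of_confusion_build(self):
        rng = np.random.default_rng(0)
        keys = list(range(200))
        verdicts = {k: ["pathogenic", "uncertain", "benign"][k % 3] for k in keys}
        truths = {k: ["pathogenic", "benign"][k % 2] for k in keys}
        shuffled = {k: truths[k] for k in rng.permutation(keys)}
        assert build_confusion(verdicts, truths) == build_confusion(verdicts, shuffled)


class TestStratified:
    def setup_data(self, rigid_advantage=True, seed=0):
        """Two synthetic methods: ours is near-perfect on rigid positions,
        the external one guesses there; both are comparable on flexible."""
        rng = np.random.default_rng(seed)
        truths, kinds = {}, {}
        ours, theirs = {}, {}
        for i in range(400):
            truth = "pathogenic" if i % 4 == 0 else "benign"
            kind = "rigid" if i < 200 else "flexible"
            truths[i], kinds[i] = truth, kind
            flip = lambda t: "pathogenic" if t == "benign" else "benign"
            if kind == "rigid" and rigid_advantage:
                ours[i] = truth
                theirs[i] = truth if rng.random() < 0.6 else flip(truth)
            else:
                ours[i] = truth if rng.random() < 0.8 else flip(truth)
                theirs[i] = truth if rng.random() < 0.8 else flip(truth)
        return truths, kinds, ours, theirs

    def test_identical_tables_identical_reports(self):
        truths, kinds, ours, _ = self.setup_data()
        reports = stratified_compare({"a": ours, "b": ours}, truths, kinds)
        for stratum in ("all", "rigid", "flexible"):
            assert reports[("a", stratum)] == reports[("b", stratum)]

    def test_planted_rigid_advantage_detected(self):
        truths, kinds, ours, theirs = self.setup_data()
        reports = stratified_compare({"ours": ours, "ext": theirs}, truths, kinds)
        gap_rigid = (
            reports[("ours", "rigid")].mcc - reports[("ext", "rigid")].mcc
        )
        gap_flex = (
            reports[("ours", "flexible")].mcc - reports[("ext", "flexible")].mcc
        )
        assert gap_rigid > gap_flex

    def test_single_class_stratum_flags_mcc(self):
        truths = {0: "benign", 1: "benign"}
        kinds = {0: "rigid", 1: "rigid"}
        verdicts = {0: "benign", 1: "pathogenic"}
        reports = stratified_compare({"m": verdicts}, truths, kinds)
        r = reports[("m", "rigid")]
        assert r.mcc is None
        assert r.accuracy == pytest.approx(0.5)

    def test_unannotated_variant_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            stratified_compare({"m": {0: "benign"}}, {0: "benign"}, {})
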
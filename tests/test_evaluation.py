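import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scouter as sc
from scouter.evaluation import _bootstrap_ci, top_k_indices


def naive_pcc(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)


class TestTopDEGs:
    def test_shifted_genes_occupy_top_ranks(self):
        rng = np.random.default_rng(0)
        x = np.tile(np.ones(10), (20, 1)) + rng.normal(0, 1e-3, size=(20, 10))
        x[10:, [2, 5, 7]] += np.array([3.0, -2.0, 4.0])
        labels = [sc.parse_label(s) for s in ["ctrl"] * 10 + ["A"] * 10]
        ds = sc.PerturbDataset(x, [f"g{i}" for i in range(10)], labels)
        deg = sc.top_degs(ds, "A", top_k=3)
        assert set(deg.genes) == {2, 5, 7}
        assert deg.genes[0] == 7  # largest |shift| first

    def test_tie_break_by_gene_index(self):
        x = np.vstack([np.zeros((3, 4)), np.zeros((3, 4))])
        labels = [sc.parse_label(s) for s in ["ctrl"] * 3 + ["A"] * 3]
        ds = sc.PerturbDataset(x, list("abcd"), labels)
        deg = sc.top_degs(ds, "A", top_k=3)
        assert deg.genes == [0, 1, 2]

    def test_matches_per_gene_brute_force(self, tiny_sim):
        ds, _, _ = tiny_sim
        pert = ds.perturbations()[0]
        cells = ds.cells_of(pert)
        ctrl = ds.control_indices
        scores = []
        for g in range(ds.n_genes):
            pm = ds.expression[cells, g].mean()
            cm = ds.expression[ctrl, g].mean()
            scores.append(abs(pm - cm))
        order = sorted(range(ds.n_genes), key=lambda g: (-scores[g], g))
        assert sc.top_degs(ds, pert, top_k=20).genes == order[:20]

    def test_provided_list_takes_precedence(self, tiny_sim):
        ds, _, _ = tiny_sim
        deg = sc.top_degs(ds, ds.perturbations()[0], top_k=3, provided=[9, 1, 4])
        assert deg.genes == [9, 1, 4] and deg.source == "provided"

    def test_absent_perturbation_raises(self, tiny_sim):
        ds, _, _ = tiny_sim
        with pytest.raises(ValueError):
            sc.top_degs(ds, "NOT_THERE", top_k=5)

    def test_top_k_indices_descending(self):
        assert top_k_indices(np.array([0.1, 5.0, 5.0, 3.0]), 3) == [1, 2, 3]


class TestMetricIdentities:
    def test_no_change_prediction_scores_exactly_one(self):
        rng = np.random.default_rng(1)
        x, c = rng.normal(size=20), rng.normal(size=20)
        assert sc.normalized_mse(x, c, c) == 1.0

    def test_perfect_prediction_scores_zero(self):
        rng = np.random.default_rng(2)
        x, c = rng.normal(size=20), rng.normal(size=20)
        assert sc.normalized_mse(x, x, c) == 0.0
        assert sc.one_minus_pcc(x, x, c) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # x=(1,0), c=(0,0), xhat=(0.5,0) -> (0.25+0)/(1+0) = 0.25
        assert sc.normalized_mse([1.0, 0.0], [0.5, 0.0], [0.0, 0.0]) == pytest.approx(0.25)

    def test_anticorrelated_prediction_scores_two(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=20)
        d = rng.normal(size=20)
        assert sc.one_minus_pcc(c + d, c - d, c) == pytest.approx(2.0)

    def test_positively_proportional_change_scores_zero(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=20)
        d = rng.normal(size=20)
        assert sc.one_minus_pcc(c + d, c + 0.3 * d, c) == pytest.approx(0.0, abs=1e-12)

    def test_pcc_matches_textbook_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x, xh, c = rng.normal(size=(3, 20))
            expected = 1.0 - naive_pcc(list(x - c), list(xh - c))
            assert sc.one_minus_pcc(x, xh, c) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_joint_rescaling_invariance(self, scale):
        rng = np.random.default_rng(6)
        x, xh, c = rng.normal(size=(3, 20))
        assert sc.normalized_mse(scale * x, scale * xh, scale * c) == pytest.approx(
            sc.normalized_mse(x, xh, c), rel=1e-9)
        assert sc.one_minus_pcc(scale * x, scale * xh, scale * c) == pytest.approx(
            sc.one_minus_pcc(x, xh, c), rel=1e-9, abs=1e-9)

    def test_undefined_metrics_raise(self):
        with pytest.raises(ZeroDivisionError):
            sc.normalized_mse([1.0, 2.0], [1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ZeroDivisionError):
            sc.one_minus_pcc([1.0, 1.0], [2.0, 1.0], [1.0, 1.0])


class TestEvaluate:
    def test_all_perfect_predictions(self, tiny_sim):
        ds, _, _ = tiny_sim
        perts = ds.perturbations()[:4]
        preds = []
        for p in perts:
            profile = ds.expression[ds.cells_of(p)].mean(axis=0)
            preds.append(sc.PredictionResult(
                perturbation=p, per_control=profile[None, :],
                mean_profile=profile, K=1, control_indices=np.array([0])))
        rep = sc.evaluate(ds, preds, train_perts=set(), n_bootstrap=100, seed=0)
        assert rep.median("normalized_mse") == 0.0
        assert rep.median("one_minus_pcc") == pytest.approx(0.0, abs=1e-12)

    def test_single_perturbation_degenerate_ci(self, tiny_sim):
        ds, _, _ = tiny_sim
        p = ds.perturbations()[0]
        profile = ds.expression[ds.cells_of(p)].mean(axis=0) + 0.01
        rep = sc.evaluate(
            ds,
            [sc.PredictionResult(perturbation=p, per_control=profile[None, :],
                                 mean_profile=profile, K=1, control_indices=np.array([0]))],
            train_perts=set(), n_bootstrap=50, seed=0)
        agg = rep.aggregates["overall"]["normalized_mse"]
        row = rep.per_perturbation[0]
        assert agg["median"] == pytest.approx(row["normalized_mse"])
        assert agg["ci50"][0] == agg["ci50"][1] == agg["median"]

    def test_subgroups_partition_the_report(self, tiny_sim):
        ds, table, _ = tiny_sim
        perts = ds.perturbations()
        train = set(perts[:3])
        preds = sc.no_change_baseline(ds, perts[3:])
        rep = sc.evaluate(ds, preds, train_perts=train, n_bootstrap=50, seed=1)
        sizes = [v["n"] for k, v in rep.aggregates.items() if k != "overall"]
        assert sum(sizes) == rep.aggregates["overall"]["n"] == len(perts[3:])

    def test_empty_predictions_rejected(self, tiny_sim):
        ds, _, _ = tiny_sim
        with pytest.raises(ValueError):
            sc.evaluate(ds, [], train_perts=set())

    def test_report_write(self, tiny_sim, tmp_path):
        import json

        ds, _, _ = tiny_sim
        rep = sc.evaluate(ds, sc.no_change_baseline(ds, ds.perturbations()),
                          train_perts=set(), n_bootstrap=20, seed=0)
        rep.write(tmp_path / "r.csv", tmp_path / "r.json")
        assert (tmp_path / "r.csv").exists()
        agg = json.loads((tmp_path / "r.json").read_text())["aggregates"]
        assert agg["overall"]["normalized_mse"]["median"] == 1.0


class TestBootstrap:
    def test_matches_naive_resampling_loop(self):
        values = np.array([0.1, 0.4, 0.2, 0.9, 0.3])
        n_boot = 2000

        rng = np.random.default_rng(42)
        lo, hi = _bootstrap_ci(values, n_boot, rng)

        # naive loop: same resampling stream, hand-rolled median + percentile
        rng2 = np.random.default_rng(42)
        draws = rng2.integers(0, values.size, size=(n_boot, values.size))
        medians = []
        for row in draws:
            sample = sorted(values[i] for i in row)
            medians.append(sample[len(sample) // 2])
        medians.sort()

        def percentile(sorted_vals, q):
            pos = (len(sorted_vals) - 1) * q / 100
            lo_i, frac = int(pos), pos - int(pos)
            if lo_i + 1 < len(sorted_vals):
                return sorted_vals[lo_i] * (1 - frac) + sorted_vals[lo_i + 1] * frac
            return sorted_vals[lo_i]

        assert lo == pytest.approx(percentile(medians, 25), abs=1e-12)
        assert hi == pytest.approx(percentile(medians, 75), abs=1e-12)
        assert lo <= np.median(values) <= hi or lo <= hi  # ordering sanity
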
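import numpy as np
import pandas as pd
import pytest

from sclb.synthetic import (
    SyntheticConfig,
    build_lr_database,
    make_ccc_truth,
    make_celltype_counts,
)
from sclb.tasks._shared import ensure_log10k
from sclb.tasks.ccc import (
    _magnitude_matrix,
    aggregate,
    metric_auprc,
    metric_odds_ratio_top,
    score_magnitude,
    score_specificity,
    top_bin_size,
)


@pytest.fixture(scope="module")
def planted_ds():
    base = make_celltype_counts(
        SyntheticConfig(n_cells=300, n_genes=120, n_types=5, seed=2)
    )
    db = build_lr_database(base.gene_meta.index, n_pairs=30, seed=3)
    ds, truth = make_ccc_truth(base, db, n_true_pairs=6, effect_fold=20.0, seed=4)
    return ensure_log10k(ds), db, truth


class TestMagnitude:
    def test_mean_of_type_means(self):
        means = np.array([[2.0, 0.0], [0.0, 4.0]])  # types x genes
        detect = np.ones((2, 2))
        score = _magnitude_matrix(means, detect, li=0, ri=1, gated=True)
        assert score[0, 1] == pytest.approx(3.0)

    def test_detection_gate_zeroes_score(self):
        means = np.array([[2.0, 4.0]])
        detect = np.array([[0.0, 1.0]])  # ligand undetected
        score = _magnitude_matrix(means, detect, li=0, ri=1, gated=True)
        assert score[0, 0] == 0.0

    def test_invariant_to_target_cell_ligand_expression(self, planted_ds):
        ds, db, _ = planted_ds
        before = score_magnitude(ds, db)
        mod = ds.copy()
        labels = np.asarray(mod.cell_meta["label"]).astype(str)
        lig = db.pairs[0][0]
        j = list(mod.gene_meta.index).index(lig)
        # perturb the ligand's log-10k values in one *target* type only
        mod.layers["log10k"][labels == "type_1", j] += 5.0
        after = score_magnitude(mod, db)
        sel = (before["ligand"] == lig) & (before["source"] != "type_1")
        pd.testing.assert_frame_equal(
            before[sel].reset_index(drop=True), after[sel].reset_index(drop=True)
        )


class TestSpecificity:
    def test_uniform_gene_sits_mid_null(self):
        ds = make_celltype_counts(
            SyntheticConfig(n_cells=300, n_genes=40, n_types=3, de_strength=0.0, seed=5)
        )
        ensure_log10k(ds)
        db = build_lr_database(ds.gene_meta.index, n_pairs=5, seed=6)
        pred = score_specificity(ds, db, n_perm=100, seed=7)
        assert pred["score"].mean() == pytest.approx(0.5, abs=0.15)

    def test_planted_pair_tops_all_permutations(self, planted_ds):
        ds, db, truth = planted_ds
        pred = score_specificity(ds, db, n_perm=100, seed=8)
        best = pred.groupby(["source", "target"])["score"].max()
        top_scores = [best.get(st, 0.0) for st in truth.positive_st]
        assert max(top_scores) >= 100 / 101 - 1e-12

    def test_planted_pair_in_top_five_percent_of_magnitude(self, planted_ds):
        ds, db, truth = planted_ds
        pred = score_magnitude(ds, db).sort_values("score", ascending=False)
        m = top_bin_size(len(pred))
        top = pred.head(m)
        hits = set(zip(top["source"], top["target"])) & truth.positive_st
        assert hits

    def test_small_n_perm_rejected(self, planted_ds):
        ds, db, _ = planted_ds
        with pytest.raises(ValueError, match="n_perm"):
            score_specificity(ds, db, n_perm=5)

    def test_fixed_seed_identical_scores(self, planted_ds):
        ds, db, _ = planted_ds
        a = score_specificity(ds, db, n_perm=20, seed=9)
        b = score_specificity(ds, db, n_perm=20, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestAggregate:
    def _pred(self):
        return pd.DataFrame(
            {
                "source": ["s", "s"],
                "target": ["t", "t"],
                "ligand": ["l1", "l2"],
                "receptor": ["r1", "r2"],
                "score": [1.0, 3.0],
            }
        )

    def test_mean_and_max(self):
        assert aggregate(self._pred(), "mean", "source_target")[0] == (("s", "t"), 2.0)
        assert aggregate(self._pred(), "max", "source_target")[0] == (("s", "t"), 3.0)

    def test_single_row_group_mean_equals_max(self):
        p = self._pred().iloc[:1]
        assert aggregate(p, "mean", "ligand_target") == aggregate(p, "max", "ligand_target")

    def test_ligand_target_level_ignores_source(self):
        p = self._pred()
        p.loc[1, "source"] = "other"
        p.loc[1, "ligand"] = "l1"
        out = aggregate(p, "mean", "ligand_target")
        assert out[0] == (("l1", "t"), 2.0)

    def test_tie_break_is_lexicographic(self):
        p = pd.DataFrame(
            {
                "source": ["b", "a"],
                "target": ["t", "t"],
                "ligand": ["l", "l"],
                "receptor": ["r", "r"],
                "score": [1.0, 1.0],
            }
        )
        out = aggregate(p, "mean", "source_target")
        assert [k for k, _ in out] == [("a", "t"), ("b", "t")]

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            aggregate(self._pred(), "mean", "bogus")


def _ranked(keys):
    return [(k, float(len(keys) - i)) for i, k in enumerate(keys)]


class TestAUPRC:
    def test_all_positives_on_top(self):
        ranked = _ranked(["p1", "p2", "n1", "n2"])
        assert metric_auprc(ranked, {"p1", "p2"}) == pytest.approx(1.0)

    def test_bruteforce_walk_example(self):
        ranked = _ranked(["p1", "n1", "p2"])
        assert metric_auprc(ranked, {"p1", "p2"}) == pytest.approx(0.8333, abs=1e-4)

    def test_everything_positive(self):
        ranked = _ranked(["a", "b", "c"])
        assert metric_auprc(ranked, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_absent_positive_counts_as_never_retrieved(self):
        ranked = _ranked(["p1", "n1"])
        assert metric_auprc(ranked, {"p1", "ghost"}) == pytest.approx(0.5)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metric_auprc(_ranked(["a"]), set())


class TestOddsRatio:
    def test_contingency_arithmetic(self):
        keys = [f"k{i}" for i in range(100)]
        positives = set(keys[:4]) | set(keys[20:26])  # 4 in the top-5 bin, 10 total
        assert metric_odds_ratio_top(_ranked(keys), positives) == pytest.approx(
            (4 * 89) / (1 * 6), abs=1e-9
        )

    def test_uniform_positives_or_near_one(self):
        rng = np.random.default_rng(0)
        ors = []
        for _ in range(200):
            keys = [f"k{i}" for i in range(100)]
            positives = set(rng.choice(keys, size=20, replace=False))
            ors.append(metric_odds_ratio_top(_ranked(keys), positives))
        assert 0.5 < np.median(ors) < 2.0

    def test_haldane_correction_keeps_finite(self):
        keys = [f"k{i}" for i in range(40)]
        positives = set(keys[:2])  # exactly fills the top bin; b == 0
        out = metric_odds_ratio_top(_ranked(keys), positives)
        assert np.isfinite(out) and out > 1

    def test_invariant_to_within_bin_permutation(self):
        keys = [f"k{i}" for i in range(40)]
        positives = {keys[1], keys[10]}
        base = metric_odds_ratio_top(_ranked(keys), positives)
        shuffled = keys[:2][::-1] + keys[2:20] + keys[20:][::-1]
        assert metric_odds_ratio_top(_ranked(shuffled), positives) == base

    def test_short_ranking_rejected(self):
        with pytest.raises(ValueError, match="20"):
            metric_odds_ratio_top(_ranked(["a"] * 10), {"a"})


class TestEndToEnd:
    @pytest.mark.parametrize("level", ["ccc_source_target", "ccc_ligand_target"])
    def test_controls_anchor_and_magnitude_beats_random(self, bench, level):
        _, table = bench(level)
        d = "synthetic_planted"
        assert table.overall[(d, "oracle_ranking")] == 1.0
        assert table.overall[(d, "random_ranking")] == 0.0
        assert table.overall[(d, "magnitude_max")] > 0.0
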
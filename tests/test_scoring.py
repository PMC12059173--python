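import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tlsarch.gene_sets import GeneSet, bundled_gene_sets, read_gene_sets_json, write_gene_sets_json
from tlsarch.matrix import CountMatrix
from tlsarch.scoring import aucell_score, scale_module_score
from tlsarch.synthetic import simulate_expression


def brute_force_auc(expr_row, gene_ids, gene_set, top_fraction):
    """Independent oracle: explicit recovery-curve integration."""
    n = len(gene_ids)
    k = int(np.ceil(top_fraction * n))
    order = sorted(range(n), key=lambda i: (-expr_row[i], i))
    hits = [gene_ids[i] in gene_set for i in order]
    m = sum(g in set(gene_ids) for g in gene_set)
    cum, area = 0, 0
    for r in range(k):
        cum += hits[r]
        area += cum
    max_area = sum(min(r + 1, m) for r in range(k))
    return area / max_area


def make_matrix(X, genes=None):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return CountMatrix(
        sp.csr_matrix(X), pd.Index([f"c{i}" for i in range(X.shape[0])]),
        pd.Index(genes),
    )


class TestAucellScore:
    def test_set_at_top_ranks_scores_one(self):
        # 3 set genes occupy the top 3 of 10 ranks, threshold 5 >= 3
        X = [[9, 8, 7, 1, 1, 1, 0, 0, 0, 0]]
        m = make_matrix(X)
        gs = GeneSet("s", frozenset(["g0", "g1", "g2"]))
        assert aucell_score(m, gs, 0.5).scores.iloc[0] == 1.0

    def test_set_outside_top_ranks_scores_zero(self):
        X = [[0, 0, 0, 5, 5, 5, 5, 5, 5, 5]]
        m = make_matrix(X)
        gs = GeneSet("s", frozenset(["g0", "g1", "g2"]))
        assert aucell_score(m, gs, 0.3).scores.iloc[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_integration(self, seed, small_gene_set):
        rng = np.random.default_rng(seed)
        X = rng.poisson(2, size=(8, 10))
        m = make_matrix(X)
        sv = aucell_score(m, small_gene_set, 0.5)
        for i in range(8):
            expected = brute_force_auc(X[i], list(m.gene_ids),
                                       small_gene_set.genes, 0.5)
            assert sv.scores.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, small_gene_set):
        rng = np.random.default_rng(3)
        X = rng.poisson(3, size=(6, 20)).astype(float)
        base = aucell_score(make_matrix(X), small_gene_set, 0.25).scores
        transformed = aucell_score(
            make_matrix(np.log1p(X) * 7.3), small_gene_set, 0.25
        ).scores
        assert np.array_equal(base.to_numpy(), transformed.to_numpy())

    def test_no_set_genes_present_rejected(self, random_count_matrix):
        m = random_count_matrix()
        with pytest.raises(ValueError, match="no genes"):
            aucell_score(m, GeneSet("s", frozenset(["absent"])), 0.1)

    def test_planted_signature_separates_positive_cells(self):
        gs = bundled_gene_sets()["chemokine_12"]
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(400)],
            "signature_positive": [i < 200 for i in range(400)],
        })
        deltas = []
        for seed in range(5):
            m = simulate_expression(cells, gs, effect=5.0, seed=seed, n_genes=300)
            s = aucell_score(m, gs, 0.1).scores
            deltas.append(s.iloc[:200].mean() - s.iloc[200:].mean())
        assert all(d > 0 for d in deltas)

    def test_null_effect_shows_no_separation(self):
        gs = bundled_gene_sets()["t_cytotoxicity"]
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(400)],
            "signature_positive": [i < 200 for i in range(400)],
        })
        m = simulate_expression(cells, gs, effect=0.0, seed=7, n_genes=300)
        s = aucell_score(m, gs, 0.1).scores
        pooled_sd = s.std()
        assert abs(s.iloc[:200].mean() - s.iloc[200:].mean()) < 0.5 * pooled_sd

    def test_effect_separation_increases_with_fold_change(self):
        gs = bundled_gene_sets()["chemokine_12"]
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(300)],
            "signature_positive": [i < 150 for i in range(300)],
        })
        seps = []
        for effect in (0.0, 1.0, 5.0):
            m = simulate_expression(cells, gs, effect=effect, seed=11, n_genes=300)
            s = aucell_score(m, gs, 0.1).scores
            seps.append(s.iloc[:150].mean() - s.iloc[150:].mean())
        assert seps[0] < seps[1] < seps[2]


class TestBundledGeneSets:
    def test_chemokine_signature_has_twelve_members(self):
        assert len(bundled_gene_sets()["chemokine_12"]) == 12

    def test_tls_imprint_contains_plasma_cell_markers(self):
        gs = bundled_gene_sets()["tls_imprint"]
        assert {"JCHAIN", "MZB1"} <= gs.genes
        assert len(gs) == 29

    def test_all_sets_round_trip_through_json(self, tmp_path):
        sets = bundled_gene_sets()
        path = tmp_path / "sets.json"
        write_gene_sets_json(sets, path)
        back = read_gene_sets_json(path)
        assert {n: s.genes for n, s in back.items()} == {
            n: s.genes for n, s in sets.items()
        }


class TestScaleModuleScore:
    def test_identical_cells_hit_minmax_guard(self):
        X = np.tile([3, 1, 4], (5, 1))
        m = make_matrix(X)
        gs = GeneSet("s", frozenset(["g0", "g1"]))
        s = scale_module_score(m, gs, list(m.cell_ids))
        assert (s == 0.5).all()

    def test_single_gene_monotone_expression_gives_monotone_scores(self):
        X = np.column_stack([np.arange(1, 7), np.full(6, 5)])
        m = make_matrix(X)
        gs = GeneSet("s", frozenset(["g0"]))
        s = scale_module_score(m, gs, list(m.cell_ids))
        assert (np.diff(s.to_numpy()) > 0).all()
        assert s.iloc[0] == 0.0 and s.iloc[-1] == 1.0

    def test_matches_hand_computed_transform(self):
        # equal library sizes; z-scoring then min-max scaling of a single
        # gene reduces to min-max of its log-normalized expression
        X = np.array([[1, 9], [5, 5], [9, 1]])
        m = make_matrix(X)
        gs = GeneSet("s", frozenset(["g0"]))
        s = scale_module_score(m, gs, list(m.cell_ids))
        l = np.log1p(np.array([1, 5, 9]) / 10 * 1e4)
        expected_mid = (l[1] - l[0]) / (l[2] - l[0])
        assert s.iloc[0] == 0.0 and s.iloc[2] == 1.0
        assert s.iloc[1] == pytest.approx(expected_mid, abs=1e-12)

    def test_constant_gene_dropped_from_mean(self):
        # g1 varies, g2 is constant across cells (after equal-library
        # normalization) and must not poison the score
        X = np.array([[1, 4, 9], [5, 4, 5], [9, 4, 1], [2, 4, 8], [6, 4, 4]])
        m = make_matrix(X)
        both = scale_module_score(m, GeneSet("s", frozenset(["g0", "g1"])),
                                  list(m.cell_ids))
        only_g0 = scale_module_score(m, GeneSet("s", frozenset(["g0"])),
                                     list(m.cell_ids))
        assert np.allclose(both.to_numpy(), only_g0.to_numpy())

    def test_order_must_be_permutation(self):
        m = make_matrix(np.ones((3, 2)))
        gs = GeneSet("s", frozenset(["g0"]))
        with pytest.raises(ValueError):
            scale_module_score(m, gs, ["c0", "c1"])
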
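import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from senatlas import (
    ModuleScorer,
    ScoringParams,
    SenescenceCaller,
    SSGSEAScorer,
    USS_SET_NAMES,
    module_score,
    score_table,
    ss_score,
    uss_call,
    uss_fractions,
)
from senatlas.scoring import z_normalize_scores


class TestRunningSumScore:
    def test_hand_example_alpha_zero(self, matrix_factory, ss_oracle):
        # genes gA=3, gB=2, gC=1, set {gA}: (1-0) + (1-0.5) + (1-1) = 1.5
        cm = matrix_factory(np.array([[3], [2], [1]]))
        score = ss_score(cm, ["g0"], ScoringParams(alpha=0.0))
        assert score[0] == pytest.approx(1.5, abs=1e-12)
        assert ss_oracle(np.array([3.0, 2, 1]), np.array([True, False, False]), 0.0) \
            == pytest.approx(1.5, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_on_random_matrices(self, matrix_factory, ss_oracle, alpha):
        rng = np.random.default_rng(42)
        X = rng.poisson(2.0, size=(15, 8))  # ties guaranteed
        cm = matrix_factory(X)
        in_set = np.zeros(15, dtype=bool)
        in_set[[1, 4, 9]] = True
        scores = ss_score(cm, ["g1", "g4", "g9"], ScoringParams(alpha=alpha))
        for j in range(8):
            expected = ss_oracle(X[:, j].astype(float), in_set, alpha)
            assert scores[j] == pytest.approx(expected, abs=1e-10)

    def test_rank_invariance(self, matrix_factory):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(30, 10))
        params = ScoringParams(alpha=0.25)
        base = ss_score(matrix_factory(X), ["g2", "g5"], params)
        # strictly increasing transforms leave every rank (and tie) unchanged;
        # scored via the estimator which accepts non-integer expression
        scorer = SSGSEAScorer({"S": ["g2", "g5"]}, [f"g{i}" for i in range(30)],
                              alpha=0.25).fit(X.T)
        for transform in (lambda v: 3 * v + 1, np.expm1, lambda v: v ** 3):
            assert scorer.transform(transform(X.T.astype(float))) == \
                pytest.approx(base[:, None], abs=1e-12)

    def test_empty_intersection_error(self, matrix_factory):
        cm = matrix_factory(np.ones((3, 2), dtype=int))
        with pytest.raises(ValueError, match="empty intersection"):
            ss_score(cm, ["nope"])

    def test_full_universe_error(self, matrix_factory):
        cm = matrix_factory(np.ones((3, 2), dtype=int))
        with pytest.raises(ValueError, match="entire gene universe"):
            ss_score(cm, ["g0", "g1", "g2"])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), alpha=st.sampled_from([0.0, 0.25, 0.5]))
    def test_property_brute_force_agreement(self, seed, alpha):
        from conftest import brute_force_ss as ss_oracle

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        expr = rng.integers(0, 5, size=n).astype(float)
        m = int(rng.integers(1, n))
        in_set = np.zeros(n, dtype=bool)
        in_set[rng.choice(n, size=m, replace=False)] = True
        from senatlas.scoring import _running_sum_scores

        got = _running_sum_scores(expr[None, :], in_set, alpha)[0]
        assert got == pytest.approx(ss_oracle(expr, in_set, alpha), abs=1e-10)


class TestModuleScore:
    def test_constant_expression_scores_zero(self, matrix_factory):
        cm = matrix_factory(np.full((50, 6), 3, dtype=int))
        scores = module_score(cm, ["g1", "g2"], ScoringParams(n_bins=5, n_ctrl=10))
        assert scores == pytest.approx(np.zeros(6), abs=1e-12)

    def test_permutation_null_centers_on_zero(self, small_sim):
        # random 50-gene sets over many seeds: grand mean within 3 SE of 0
        matrix, _, _, _ = small_sim
        rng = np.random.default_rng(0)
        means = []
        for seed in range(100):
            genes = rng.choice(matrix.gene_ids, size=50, replace=False)
            s = module_score(matrix, list(genes), ScoringParams(seed=seed))
            means.append(s.mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_set_equal_to_bin_has_zero_expectation(self, matrix_factory):
        rng = np.random.default_rng(3)
        X = rng.poisson(rng.lognormal(0, 1, 60)[:, None], size=(60, 40))
        cm = matrix_factory(X)
        from senatlas.scoring import _bin_genes
        from senatlas.scoring import log_normalize

        bins = _bin_genes(log_normalize(cm).mean(axis=0), 6)
        bin_genes = [f"g{i}" for i in np.flatnonzero(bins == 2)]
        means = [
            module_score(cm, bin_genes, ScoringParams(n_bins=6, n_ctrl=20, seed=s)).mean()
            for s in range(40)
        ]
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means)) + 1e-12
        assert abs(means.mean()) < 3 * se

    def test_absent_gene_error(self, matrix_factory):
        cm = matrix_factory(np.ones((5, 3), dtype=int))
        with pytest.raises(KeyError, match="absent"):
            module_score(cm, ["g0", "nope"], ScoringParams(n_bins=2))

    def test_n_bins_exceeds_genes_error(self, matrix_factory):
        cm = matrix_factory(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError, match="n_bins"):
            module_score(cm, ["g0"], ScoringParams(n_bins=10))

    def test_cross_check_against_scanpy(self, small_sim):
        scanpy = pytest.importorskip("scanpy")
        matrix, _, sets, _ = small_sim
        ours = module_score(matrix, sets["SM"], ScoringParams(seed=1))
        ad = matrix.to_anndata()
        scanpy.pp.normalize_total(ad, target_sum=1e4)
        scanpy.pp.log1p(ad)
        scanpy.tl.score_genes(ad, sets["SM"], ctrl_size=100, n_bins=24, random_state=0)
        r = np.corrcoef(ours, ad.obs["score"])[0, 1]
        assert r > 0.95


def _score_frame(scores: np.ndarray, cell_ids) -> pd.DataFrame:
    frames = []
    for j, name in enumerate(USS_SET_NAMES):
        frames.append(pd.DataFrame(
            {"cell_id": cell_ids, "set": name, "score": scores[:, j]}))
    return pd.concat(frames, ignore_index=True)


def _annotation(cell_ids, cell_type="T", age="young"):
    return pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": "s1",
        "age_group": age,
        "cell_type": cell_type,
    })


class TestUSSCall:
    def test_top_cell_flagged_at_k6(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(4, 6))
        scores[2] = scores.max() + 1  # one cell tops every set
        cells = [f"c{i}" for i in range(4)]
        calls = uss_call(_score_frame(scores, cells), _annotation(cells), k=6)
        assert calls.set_index("cell_id")["senescent"].to_dict() == {
            "c0": False, "c1": False, "c2": True, "c3": False}

    def test_fraction_bound_and_monotone_in_k(self):
        rng = np.random.default_rng(1)
        cells = [f"c{i}" for i in range(999)]
        scores = _score_frame(rng.normal(size=(999, 6)), cells)
        ann = _annotation(cells)
        prev = 1.0
        for k in range(1, 7):
            frac = uss_call(scores, ann, k=k)["senescent"].mean()
            assert frac <= prev + 1e-12  # non-increasing in k
            prev = frac
        # the median-split bound applies when all six sets are required:
        # flagged cells are a subset of each set's strict upper half
        assert prev <= 0.5 + 1e-12

    def test_ties_at_median_fall_in_lower_half(self):
        cells = [f"c{i}" for i in range(4)]
        scores = _score_frame(np.ones((4, 6)), cells)  # all tied at the median
        calls = uss_call(scores, _annotation(cells), k=1)
        assert not calls["senescent"].any()

    def test_missing_set_error(self):
        cells = ["c0", "c1"]
        scores = _score_frame(np.zeros((2, 6)), cells)
        scores = scores[scores["set"] != "IR"]
        with pytest.raises(KeyError, match="IR"):
            uss_call(scores, _annotation(cells))

    def test_small_cell_type_skipped_with_warning(self, caplog):
        cells = [f"c{i}" for i in range(5)]
        scores = _score_frame(np.random.default_rng(0).normal(size=(5, 6)), cells)
        ann = _annotation(cells)
        ann.loc[4, "cell_type"] = "Rare"
        with caplog.at_level("WARNING"):
            calls = uss_call(scores, ann)
        assert "Rare" in caplog.text
        assert set(calls["cell_id"]) == set(cells[:4])

    def test_invalid_k(self):
        cells = ["c0", "c1"]
        scores = _score_frame(np.zeros((2, 6)), cells)
        with pytest.raises(ValueError, match="k must be"):
            uss_call(scores, _annotation(cells), k=7)

    def test_fractions_summary(self):
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(100)]
        scores = _score_frame(rng.normal(size=(100, 6)), cells)
        ann = _annotation(cells)
        ann.loc[50:, "age_group"] = "aged"
        calls = uss_call(scores, ann, k=1)
        frac = uss_fractions(calls, ann)
        assert set(frac["age_group"]) == {"young", "aged"}
        assert (frac["n_cells"] == 50).all()

    def test_z_normalization_preserves_calls(self):
        rng = np.random.default_rng(3)
        cells = [f"c{i}" for i in range(80)]
        scores = _score_frame(rng.normal(size=(80, 6)), cells)
        ann = _annotation(cells)
        base = uss_call(scores, ann, k=3)
        z = z_normalize_scores(scores, ann)
        z_calls = uss_call(
            z.drop(columns=["score", "cell_type"]).rename(columns={"score_z": "score"}),
            ann, k=3)
        assert (base["senescent"].to_numpy() == z_calls["senescent"].to_numpy()).all()


class TestEstimators:
    def test_ssgsea_scorer_matches_function(self, matrix_factory):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(20, 9))  # genes x cells
        cm = matrix_factory(X)
        gene_ids = [f"g{i}" for i in range(20)]
        scorer = SSGSEAScorer({"A": ["g0", "g3"], "B": ["g5"]}, gene_ids).fit(X.T)
        out = scorer.transform(X.T)
        assert out[:, 0] == pytest.approx(ss_score(cm, ["g0", "g3"]), abs=1e-12)
        assert out[:, 1] == pytest.approx(ss_score(cm, ["g5"]), abs=1e-12)
        assert scorer.get_feature_names_out().tolist() == ["A", "B"]
        clone(scorer)  # sklearn param contract

    def test_module_scorer_matches_function(self, matrix_factory):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(40, 12))
        cm = matrix_factory(X)
        gene_ids = [f"g{i}" for i in range(40)]
        est = ModuleScorer({"A": ["g0", "g7"]}, gene_ids, n_bins=4, n_ctrl=5, seed=9)
        out = est.fit(X.T).transform(X.T)
        ref = module_score(cm, ["g0", "g7"], ScoringParams(n_bins=4, n_ctrl=5, seed=9))
        assert out[:, 0] == pytest.approx(ref, abs=1e-12)

    def test_senescence_caller_matches_uss_call(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(60, 6))
        cells = [f"c{i}" for i in range(60)]
        types = np.array(["A"] * 30 + ["B"] * 30)
        ann = _annotation(cells)
        ann["cell_type"] = types
        ref = uss_call(_score_frame(scores, cells), ann, k=4)
        est = SenescenceCaller(k=4).fit(scores, types)
        pred = est.predict(scores, types)
        ref_flags = ref.set_index("cell_id").loc[cells, "senescent"].to_numpy()
        assert (pred == ref_flags).all()
        assert est.decision_function(scores, types).max() <= 6


class TestScoreTable:
    def test_shared_ranking_matches_per_set_scores(self, matrix_factory):
        rng = np.random.default_rng(5)
        X = rng.poisson(2.0, size=(30, 7))
        cm = matrix_factory(X)
        sets = {"A": ["g0", "g2"], "B": ["g5", "g9", "g11"]}
        table = score_table(cm, sets, method="ssgsea")
        for name, genes in sets.items():
            ref = ss_score(cm, genes)
            got = table[table["set"] == name]["score"].to_numpy()
            assert got == pytest.approx(ref, abs=1e-12)

    def test_unknown_method(self, matrix_factory):
        cm = matrix_factory(np.ones((4, 2), dtype=int))
        with pytest.raises(ValueError, match="unknown scoring method"):
            score_table(cm, {"A": ["g0"]}, method="gsva")
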